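"""Feature interdependency audit via Spearman rank correlation.

Cumulative DVH features are nested volumes (everything above 20 Gy is also
above 5 Gy), so they are strongly rank-correlated; differential bins do
not share volume and correlate far less. The matrix produced here is the
quantitative record of that multicollinearity.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = ["CorrelationMatrix", "spearman_matrix", "group_dependency_summary",
           "plot_heatmap"]


@dataclass(frozen=True)
class CorrelationMatrix:
    """Symmetric Spearman rho matrix over named features."""

    feature_names: tuple[str, ...]
    values: np.ndarray

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        n = len(self.feature_names)
        if v.shape != (n, n):
            raise ValueError("matrix shape must match feature count")
        if not np.allclose(v, v.T, atol=1e-12):
            raise ValueError("correlation matrix must be symmetric")
        if np.any(np.abs(v) > 1 + 1e-12) or not np.allclose(np.diag(v), 1.0):
            raise ValueError("rho must lie in [-1, 1] with unit diagonal")
        object.__setattr__(self, "values", v)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=list(self.feature_names),
                            columns=list(self.feature_names))

    def rho(self, a: str, b: str) -> float:
        i = self.feature_names.index(a)
        j = self.feature_names.index(b)
        return float(self.values[i, j])


def spearman_matrix(table: pd.DataFrame,
                    feature_subset: list[str] | None = None) -> CorrelationMatrix:
    """Pairwise Spearman rho (mid-ranks for ties) over the given columns.

    Raises on constant columns, whose rank correlation is undefined.
    """
    cols = list(feature_subset) if feature_subset is not None else list(table.columns)
    if len(table) < 3:
        raise ValueError("need at least 3 rows for a meaningful rank correlation")
    sub = table[cols]
    if sub.isna().any().any():
        raise ValueError("feature table contains missing values")
    for c in cols:
        if sub[c].nunique() == 1:
            raise ValueError(f"constant column {c!r}: Spearman rho undefined")
    if len(cols) == 1:
        rho = np.ones((1, 1))
    elif len(cols) == 2:
        r, _ = sps.spearmanr(sub.iloc[:, 0], sub.iloc[:, 1])
        rho = np.array([[1.0, r], [r, 1.0]])
    else:
        rho, _ = sps.spearmanr(sub.to_numpy(), axis=0)
    np.fill_diagonal(rho, 1.0)
    return CorrelationMatrix(tuple(cols), rho)


def group_dependency_summary(cm: CorrelationMatrix,
                             groups: dict[str, list[str]]) -> dict[str, float]:
    """Mean absolute off-diagonal rho within each named feature group."""
    out = {}
    for name, feats in groups.items():
        if len(feats) < 2:
            raise ValueError(f"group {name!r} needs at least 2 features")
        idx = [cm.feature_names.index(f) for f in feats]
        block = cm.values[np.ix_(idx, idx)]
        off = block[~np.eye(len(idx), dtype=bool)]
        out[name] = float(np.abs(off).mean())
    return out


def plot_heatmap(cm: CorrelationMatrix, path, title: str = "") -> None:
    """Render the matrix as a heat map image (presentation only)."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    n = len(cm.feature_names)
    fig, ax = plt.subplots(figsize=(max(4, 0.35 * n), max(3.5, 0.3 * n)))
    im = ax.imshow(cm.values, vmin=-1, vmax=1, cmap="RdBu_r")
    ax.set_xticks(range(n), cm.feature_names, rotation=90, fontsize=7)
    ax.set_yticks(range(n), cm.feature_names, fontsize=7)
    if title:
        ax.set_title(title)
    fig.colorbar(im, ax=ax, label="Spearman rho")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
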