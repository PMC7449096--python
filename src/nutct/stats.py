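"""Dataset-level analyses of a per-nut trait table.

Descriptive statistics per trait, the Pearson correlation matrix with
two-sided t-distribution p-values, a standardized PCA, and per-accession
rankings used to pick superior genotypes (e.g. thinnest shell, highest
kernel filling ratio).  Statistics are computed over individual nut rows;
rankings aggregate to accession means.  Sample (n-1) standard deviations
are used throughout.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd
from scipy import stats as sps
from sklearn.decomposition import PCA

from .volume_io import TRAIT_COLUMNS

__all__ = [
    "summarize_traits",
    "correlation_matrix",
    "run_pca",
    "top_accessions",
    "PCAResult",
]


def _trait_frame(table: pd.DataFrame, traits: list[str] | None = None) -> pd.DataFrame:
    cols = traits if traits is not None else [
        c for c in TRAIT_COLUMNS if c in table.columns
    ]
    missing = [c for c in cols if c not in table.columns]
    if missing:
        raise ValueError(f"unknown trait column(s): {', '.join(missing)}")
    frame = table[cols]
    bad = [c for c in cols if not np.issubdtype(frame[c].dtype, np.number)]
    if bad:
        raise ValueError(f"non-numeric trait column(s): {', '.join(bad)}")
    return frame


def summarize_traits(
    table: pd.DataFrame, traits: list[str] | None = None
) -> pd.DataFrame:
    """Per-trait mean, sample SD, min and max over all nut rows.

    A single-row table yields SD = 0 with ``sd_defined = False``.
    """
    frame = _trait_frame(table, traits)
    if len(frame) < 1:
        raise ValueError("trait table is empty")
    single = len(frame) == 1
    out = pd.DataFrame(
        {
            "trait": frame.columns,
            "mean": frame.mean().to_numpy(),
            "sd": np.zeros(frame.shape[1]) if single else frame.std(ddof=1).to_numpy(),
            "min": frame.min().to_numpy(),
            "max": frame.max().to_numpy(),
            "n": len(frame),
            "sd_defined": not single,
        }
    )
    return out


def correlation_matrix(
    table: pd.DataFrame,
    traits: list[str] | None = None,
    bonferroni: bool = False,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Pearson r and two-sided p-values for every trait pair.

    Zero-variance columns are rejected explicitly rather than silently
    yielding r = 0.  ``bonferroni`` multiplies p-values by the number of
    distinct pairs (off by default: raw p-values are conventional here).
    """
    frame = _trait_frame(table, traits)
    n = len(frame)
    if n < 3:
        raise ValueError("need at least 3 rows for correlations")
    sd = frame.std(ddof=1)
    flat = sd[sd == 0].index.tolist()
    if flat:
        raise ValueError(
            f"zero-variance column(s) make Pearson r undefined: {', '.join(flat)}"
        )
    r = frame.corr(method="pearson")
    rv = np.clip(r.to_numpy(), -1.0, 1.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        tstat = rv * np.sqrt((n - 2) / (1.0 - rv**2))
    p = 2.0 * sps.t.sf(np.abs(tstat), df=n - 2)
    np.fill_diagonal(p, 0.0)
    if bonferroni:
        m = rv.shape[0] * (rv.shape[0] - 1) // 2
        p = np.minimum(p * m, 1.0)
        np.fill_diagonal(p, 0.0)
    pmat = pd.DataFrame(p, index=r.index, columns=r.columns)
    return r, pmat


@dataclasses.dataclass
class PCAResult:
    explained_variance_pct: np.ndarray
    loadings: pd.DataFrame  # traits x components
    scores: pd.DataFrame  # individuals x components
    squared_cosines: pd.DataFrame  # individuals x components


def run_pca(
    table: pd.DataFrame,
    traits: list[str] | None = None,
    n_components: int | None = None,
) -> PCAResult:
    """Standardized PCA of the trait table.

    Traits are centred and scaled to unit (sample) variance before the
    eigendecomposition; explained-variance percentages over all components
    sum to 100.  Component signs are fixed so each component's
    largest-magnitude loading is positive.  Squared cosines give the quality
    of representation of each individual on each component.
    """
    frame = _trait_frame(table, traits)
    if len(frame) < 3 or frame.shape[1] < 2:
        raise ValueError("need >= 3 rows and >= 2 traits for PCA")
    sd = frame.std(ddof=1)
    flat = sd[sd == 0].index.tolist()
    if flat:
        raise ValueError(f"constant column(s): {', '.join(flat)}")
    X = (frame - frame.mean()) / sd
    k_full = min(len(frame) - 1, frame.shape[1])
    pca = PCA(n_components=k_full, svd_solver="full")
    scores = pca.fit_transform(X.to_numpy())
    comps = pca.components_  # (k, n_traits)
    # deterministic sign: largest |loading| positive per component
    for i in range(comps.shape[0]):
        j = int(np.argmax(np.abs(comps[i])))
        if comps[i, j] < 0:
            comps[i] *= -1
            scores[:, i] *= -1
    k = k_full if n_components is None else min(n_components, k_full)
    evr = pca.explained_variance_ratio_ * 100.0
    names = [f"PC{i + 1}" for i in range(k_full)]
    loadings = pd.DataFrame(comps.T, index=frame.columns, columns=names)
    scores_df = pd.DataFrame(scores, index=frame.index, columns=names)
    d2 = (scores**2).sum(axis=1, keepdims=True)
    cos2 = pd.DataFrame(scores**2 / d2, index=frame.index, columns=names)
    return PCAResult(
        explained_variance_pct=evr[:k] if n_components else evr,
        loadings=loadings.iloc[:, :k],
        scores=scores_df.iloc[:, :k],
        squared_cosines=cos2.iloc[:, :k],
    )


def top_accessions(
    table: pd.DataFrame, trait: str, direction: str = "asc", n: int = 10
) -> pd.DataFrame:
    """Accessions ranked by their mean of one trait (± sample SD).

    ``direction='asc'`` ranks smallest-first (e.g. thinnest shell),
    ``'desc'`` largest-first (e.g. highest filling ratio).
    """
    if "accession_id" not in table.columns:
        raise ValueError("table has no accession_id column")
    if trait not in table.columns:
        raise ValueError(f"unknown trait name: {trait}")
    if direction not in ("asc", "desc"):
        raise ValueError("direction must be 'asc' or 'desc'")
    grouped = table.groupby("accession_id")[trait]
    out = pd.DataFrame(
        {
            "accession_id": grouped.mean().index,
            "mean": grouped.mean().to_numpy(),
            "sd": grouped.std(ddof=1).fillna(0.0).to_numpy(),
            "n_nuts": grouped.count().to_numpy(),
        }
    )
    out = out.sort_values(
        ["mean", "accession_id"], ascending=[direction == "asc", True]
    ).head(n)
    return out.reset_index(drop=True)
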