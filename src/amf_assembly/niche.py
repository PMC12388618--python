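"""Habitat generalist/specialist classification via Levins niche breadth.

For OTU j with per-sample proportions ``P_ij = x_ij / sum_i x_ij`` the Levins
breadth is ``B_j = 1 / sum_i P_ij**2`` — the effective number of samples
(habitats) the OTU occupies, between 1 (a point niche) and the number of
samples (perfectly even occupancy). Each OTU's observed breadth is compared
with the 95% interval of breadths recomputed on null community matrices; an
OTU above the upper bound is a habitat generalist, below the lower bound a
specialist, otherwise neutral.

The default null ("fixed_margins") redistributes the counts while conserving
every sample total and every OTU total exactly, drawing each null matrix
row-by-row from the multivariate hypergeometric distribution (Patefield's
r2dtable scheme). Under this null an OTU's breadth reflects only the evenness
expected from its total abundance and the sample depths, so departures mark
genuine habitat preference. An alternative null ("shuffle_rows") permutes
each sample's abundances across OTUs and is usable with non-integer
(relative) tables.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .data_io import CommunityTable

logger = logging.getLogger(__name__)

__all__ = ["NicheClassification", "levins_breadth", "classify_generalists_specialists"]


@dataclass(frozen=True)
class NicheClassification:
    otu_id: str
    breadth_observed: float
    null_lower_95: float
    null_upper_95: float
    label: str  # {"generalist", "specialist", "neutral"}
    n_permutations: int

    def __post_init__(self):
        if self.null_lower_95 > self.null_upper_95:
            raise ValueError("lower CI bound exceeds upper bound")
        expected = _label(self.breadth_observed, self.null_lower_95, self.null_upper_95)
        if self.label != expected:
            raise ValueError(f"label {self.label!r} inconsistent with CI (expected {expected!r})")


def _label(observed: float, lower: float, upper: float) -> str:
    if observed > upper:
        return "generalist"
    if observed < lower:
        return "specialist"
    return "neutral"


def _breadths(counts: np.ndarray) -> np.ndarray:
    """Levins breadth per column; NaN for all-zero columns."""
    colsum = counts.sum(axis=0)
    sumsq = (counts.astype(float) ** 2).sum(axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        return np.where(colsum > 0, colsum.astype(float) ** 2 / sumsq, np.nan)


def levins_breadth(table: CommunityTable) -> dict:
    """Levins breadth per OTU; OTUs with zero total abundance are dropped."""
    if table.n_samples < 1:
        raise ValueError("need at least one sample")
    b = _breadths(table.counts)
    dropped = [table.otu_ids[j] for j in np.flatnonzero(np.isnan(b))]
    if dropped:
        logger.warning("dropping %d zero-total OTUs from breadth output", len(dropped))
    return {o: float(b[j]) for j, o in enumerate(table.otu_ids) if not np.isnan(b[j])}


def sample_fixed_margin_matrix(counts: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """One random integer matrix with the same row and column sums as counts.

    Rows are filled sequentially by multivariate hypergeometric draws from
    the remaining column totals (Patefield's algorithm), which samples the
    distribution of an independence-model table conditioned on its margins.
    """
    n, _ = counts.shape
    rowsum = counts.sum(axis=1)
    remaining = counts.sum(axis=0).copy()
    out = np.empty_like(counts)
    for i in range(n - 1):
        out[i] = rng.multivariate_hypergeometric(remaining, int(rowsum[i]))
        remaining -= out[i]
    out[n - 1] = remaining
    return out


def _null_breadths_fixed_margins(counts, n_perm, rng):
    out = np.empty((n_perm, counts.shape[1]))
    for k in range(n_perm):
        out[k] = _breadths(sample_fixed_margin_matrix(counts, rng))
    return out


def _null_breadths_shuffle_rows(counts, n_perm, rng):
    out = np.empty((n_perm, counts.shape[1]))
    for k in range(n_perm):
        out[k] = _breadths(rng.permuted(counts, axis=1))
    return out


def classify_generalists_specialists(
    table: CommunityTable,
    n_permutations: int = 1000,
    alpha: float = 0.05,
    seed: int = 0,
    null_model: str = "fixed_margins",
) -> list:
    """Classify OTUs as habitat generalists/specialists/neutral.

    Parameters
    ----------
    table : CommunityTable
        Count matrix (integer counts required for the fixed-margin null).
    n_permutations : int
        Number of null matrices (>= 100).
    alpha : float
        Two-sided null interval level (default 0.05 -> 2.5/97.5 percentiles).
    seed : int
        Makes the null draws reproducible.
    null_model : {"fixed_margins", "shuffle_rows"}
        "fixed_margins" conserves all row and column sums exactly;
        "shuffle_rows" permutes each sample's abundances across OTUs (works
        on relative tables).

    Returns
    -------
    list of NicheClassification, one per OTU with positive total abundance.
    """
    if table.n_samples < 2:
        raise ValueError("need at least 2 samples to classify niche breadth")
    if n_permutations < 100:
        raise ValueError("n_permutations must be >= 100")
    counts = table.counts
    rng = np.random.default_rng(seed)
    if null_model == "fixed_margins":
        if not np.allclose(counts, np.round(counts)):
            raise ValueError(
                "fixed-margin null requires integer counts; use "
                "null_model='shuffle_rows' for relative-abundance tables"
            )
        imat = np.round(counts).astype(np.int64)
        null_b = _null_breadths_fixed_margins(imat, n_permutations, rng)
    elif null_model == "shuffle_rows":
        null_b = _null_breadths_shuffle_rows(counts, n_permutations, rng)
    else:
        raise ValueError(f"unknown null_model {null_model!r}")

    obs = _breadths(counts)
    keep = ~np.isnan(obs)
    if not np.all(keep):
        logger.warning("dropping %d zero-total OTUs", int((~keep).sum()))
    lo = np.nanpercentile(null_b, 100 * alpha / 2, axis=0)
    hi = np.nanpercentile(null_b, 100 * (1 - alpha / 2), axis=0)
    out = []
    for j in np.flatnonzero(keep):
        out.append(
            NicheClassification(
                otu_id=table.otu_ids[j],
                breadth_observed=float(obs[j]),
                null_lower_95=float(lo[j]),
                null_upper_95=float(hi[j]),
                label=_label(obs[j], lo[j], hi[j]),
                n_permutations=n_permutations,
            )
        )
    return out
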