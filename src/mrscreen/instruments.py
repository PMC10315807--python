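"""Instrument selection for two-sample MR.

A SNP qualifies as an instrument when it is associated with the exposure
(p < 1e-5 here, a relaxed threshold suited to metabolite GWAS), is
approximately independent of the other instruments (greedy LD clumping at
r² > 0.1 within 500 kb), and is strong (per-SNP F >= 10).  SNPs associated
with the outcome (p < 1e-5) are excluded so that instruments can plausibly
act on the outcome only through the exposure, and exposures retaining fewer
than three instruments are flagged insufficient rather than estimated.

Variance explained by one SNP:

    R² = 2β²·EAF(1−EAF) / (2β²·EAF(1−EAF) + 2·se²·N·EAF(1−EAF))

which cancels algebraically to β² / (β² + N·se²), so R² is computable even
without allele frequencies.  Instrument strength:

    F = (N − k − 1)/k · R²/(1 − R²)

with k = 1 for the per-SNP filter (k equal to the instrument count gives the
aggregate F, also reported).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .gwas_data import (
    GwasTable,
    HarmonizedSet,
    NoOverlapError,
    VariantAssociation,
    harmonize_pair,
)

__all__ = [
    "SelectionConfig",
    "Instrument",
    "LdMatrix",
    "MissingLdError",
    "variance_explained",
    "f_statistic",
    "clump",
    "select_instruments",
    "SelectionResult",
    "filter_confounders",
]


class MissingLdError(KeyError):
    """LD for an in-window SNP pair was requested but not available."""


@dataclass(frozen=True)
class SelectionConfig:
    """Thresholds governing instrument selection (defaults follow the study design)."""

    p_exposure: float = 1e-5          # genome-wide relaxed exposure threshold
    clump_r2: float = 0.1             # remove if r2 > clump_r2
    clump_window_kb: float = 500.0
    f_min: float = 10.0
    p_outcome_exclude: float = 1e-5
    min_snps: int = 3                 # "more than two SNPs"
    k_for_f: int = 1                  # per-SNP F; k = J gives the aggregate F

    def __post_init__(self) -> None:
        if min(self.p_exposure, self.clump_r2, self.clump_window_kb,
               self.f_min, self.p_outcome_exclude) <= 0:
            raise ValueError("selection thresholds must be positive")
        if self.min_snps < 1:
            raise ValueError("min_snps must be >= 1")


@dataclass(frozen=True)
class Instrument:
    """A selected instrument: the exposure association plus strength metrics."""

    variant: VariantAssociation
    r2: float
    f_stat: float

    @property
    def snp_id(self) -> str:
        return self.variant.snp_id


def variance_explained(beta, se, n, eaf=None):
    """Variance in the exposure explained by one SNP.

    Evaluates the frequency-weighted form when ``eaf`` is given; the
    2·EAF(1−EAF) factor cancels, so the result equals β²/(β² + N·se²)
    either way.  Vectorizes over numpy arrays.
    """
    beta = np.asarray(beta, dtype=float)
    se = np.asarray(se, dtype=float)
    n = np.asarray(n, dtype=float)
    if np.any(se <= 0):
        raise ValueError("se must be > 0")
    if np.any(n < 2):
        raise ValueError("n must be >= 2")
    if eaf is not None:
        eaf = np.asarray(eaf, dtype=float)
        if np.any((eaf <= 0) | (eaf >= 1)):
            raise ValueError("eaf must lie strictly in (0,1) for the weighted form")
        num = 2.0 * beta**2 * eaf * (1.0 - eaf)
        den = num + 2.0 * se**2 * n * eaf * (1.0 - eaf)
        out = num / den
    else:
        out = beta**2 / (beta**2 + n * se**2)
    return out.item() if out.ndim == 0 else out


def f_statistic(r2, n, k: int = 1):
    """F = (N−k−1)/k · R²/(1−R²); per-SNP strength uses k = 1."""
    r2 = np.asarray(r2, dtype=float)
    n = np.asarray(n, dtype=float)
    if k < 1:
        raise ValueError("k must be >= 1")
    if np.any((r2 < 0) | (r2 >= 1)):
        raise ValueError("r2 must lie in [0, 1)")
    if np.any(n <= k + 1):
        raise ValueError("n must exceed k + 1")
    out = (n - k - 1) / k * r2 / (1.0 - r2)
    return out.item() if out.ndim == 0 else out


class LdMatrix:
    """In-memory symmetric matrix of pairwise r² keyed by rsID."""

    def __init__(self, snp_ids: Sequence[str], r2: np.ndarray):
        r2 = np.asarray(r2, dtype=float)
        if r2.shape != (len(snp_ids), len(snp_ids)):
            raise ValueError("r2 matrix shape does not match snp id count")
        if not np.allclose(r2, r2.T):
            raise ValueError("r2 matrix must be symmetric")
        if not np.allclose(np.diag(r2), 1.0):
            raise ValueError("r2 matrix must have unit diagonal")
        if np.any((r2 < 0) | (r2 > 1 + 1e-12)):
            raise ValueError("r2 entries must lie in [0, 1]")
        self.snp_ids = list(snp_ids)
        self._idx = {s: i for i, s in enumerate(self.snp_ids)}
        self._r2 = r2

    def r2(self, a: str, b: str) -> float:
        try:
            return float(self._r2[self._idx[a], self._idx[b]])
        except KeyError as exc:
            raise MissingLdError(f"no LD entry for pair ({a}, {b})") from exc

    @classmethod
    def from_tsv(cls, path) -> "LdMatrix":
        df = pd.read_csv(path, sep="\t", index_col=0)
        return cls(list(df.index.astype(str)), df.to_numpy(float))

    def to_tsv(self, path) -> None:
        pd.DataFrame(self._r2, index=self.snp_ids, columns=self.snp_ids).to_csv(path, sep="\t")


def _in_window(a: VariantAssociation, b: VariantAssociation, window_kb: float) -> bool:
    # Missing positions are treated conservatively as in-window; different
    # chromosomes are never in-window.
    if a.chrom is not None and b.chrom is not None and a.chrom != b.chrom:
        return False
    if a.pos is None or b.pos is None:
        return True
    return abs(a.pos - b.pos) <= window_kb * 1000.0


def clump(
    candidates: Sequence[VariantAssociation],
    ld,
    clump_r2: float = 0.1,
    window_kb: float = 500.0,
) -> list[str]:
    """Greedy p-value-ranked LD clumping.

    Repeatedly takes the smallest-p remaining SNP as index and removes every
    remaining SNP within ``window_kb`` whose r² with it exceeds ``clump_r2``.
    Ties break by (p, position, rsID) so output is order-invariant.  A
    missing LD entry for an in-window pair raises :class:`MissingLdError`.
    """
    order = sorted(
        candidates,
        key=lambda v: (v.pvalue, v.pos if v.pos is not None else float("inf"), v.snp_id),
    )
    retained: list[str] = []
    remaining = list(order)
    while remaining:
        index = remaining.pop(0)
        retained.append(index.snp_id)
        survivors = []
        for other in remaining:
            if _in_window(index, other, window_kb):
                if ld.r2(index.snp_id, other.snp_id) > clump_r2:
                    continue
            survivors.append(other)
        remaining = survivors
    return retained


@dataclass
class SelectionResult:
    """Instruments surviving the full selection pipeline, with an exhaustive audit."""

    exposure_id: str
    instruments: list[Instrument]
    harmonized: HarmonizedSet | None
    audit: dict[str, list[str]] = field(default_factory=dict)
    sufficient: bool = True
    n_significant: int = 0
    aggregate_f: float | None = None

    @property
    def n_instruments(self) -> int:
        return len(self.instruments)


def select_instruments(
    exposure: GwasTable,
    outcome: GwasTable,
    ld,
    config: SelectionConfig | None = None,
) -> SelectionResult:
    """Run the instrument-selection pipeline for one exposure.

    Stages: exposure p-value filter -> LD clumping -> R²/F computation and
    weak-instrument removal -> harmonization against the outcome ->
    outcome-association exclusion -> minimum-count check.  Every removal is
    recorded under its stage; survivors + removals = significant SNPs.
    An exposure with fewer than ``min_snps`` survivors is returned with
    ``sufficient=False`` rather than raising, so a many-exposure screen can
    continue.
    """
    cfg = config or SelectionConfig()
    audit: dict[str, list[str]] = {}

    sig = [r for r in exposure.records if r.pvalue < cfg.p_exposure]
    n_sig = len(sig)

    kept_ids = clump(sig, ld, cfg.clump_r2, cfg.clump_window_kb) if sig else []
    kept_set = set(kept_ids)
    audit["clumped"] = [r.snp_id for r in sig if r.snp_id not in kept_set]
    clumped = [r for r in sig if r.snp_id in kept_set]

    strong: list[Instrument] = []
    audit["weak_f"] = []
    for rec in clumped:
        r2 = variance_explained(rec.beta, rec.se, rec.n, rec.eaf)
        f = f_statistic(r2, rec.n, cfg.k_for_f)
        if f < cfg.f_min:
            audit["weak_f"].append(rec.snp_id)
        else:
            strong.append(Instrument(variant=rec, r2=r2, f_stat=f))

    harmonized: HarmonizedSet | None = None
    if strong:
        try:
            harmonized = harmonize_pair(exposure, outcome, [i.snp_id for i in strong])
        except NoOverlapError:
            harmonized = None
    if harmonized is None:
        audit["harmonization"] = [i.snp_id for i in strong]
        audit["outcome_associated"] = []
        return SelectionResult(
            exposure_id=exposure.trait_id, instruments=[], harmonized=None,
            audit=audit, sufficient=False, n_significant=n_sig,
        )
    audit["harmonization"] = [s for s, _ in harmonized.dropped]

    keep = harmonized.df["py"] >= cfg.p_outcome_exclude
    audit["outcome_associated"] = list(harmonized.df.loc[~keep, "snp_id"])
    harmonized = harmonized.subset(
        harmonized.df.loc[keep, "snp_id"], dropped_reason="outcome_associated")

    final_ids = set(harmonized.snp_ids)
    instruments = [i for i in strong if i.snp_id in final_ids]
    sufficient = len(instruments) >= cfg.min_snps

    agg_f = None
    if instruments:
        r2_sum = min(sum(i.r2 for i in instruments), 1.0 - 1e-12)
        n_med = float(np.median([i.variant.n for i in instruments]))
        j = len(instruments)
        if n_med > j + 1:
            agg_f = f_statistic(r2_sum, n_med, k=j)

    return SelectionResult(
        exposure_id=exposure.trait_id,
        instruments=instruments,
        harmonized=harmonized if sufficient else harmonized,
        audit=audit,
        sufficient=sufficient,
        n_significant=n_sig,
        aggregate_f=agg_f,
    )


def filter_confounders(
    harmonized: HarmonizedSet,
    confounder_table: pd.DataFrame | None,
    p_threshold: float = 1e-5,
) -> tuple[HarmonizedSet, pd.DataFrame]:
    """Drop instruments associated with a known confounder at p < threshold.

    ``confounder_table`` has columns ``snp, trait, pvalue`` (a locally
    supplied export of confounder-association lookups).  Returns the filtered
    set plus a frame naming the removed SNPs and the traits implicating them.
    An empty or missing table is the identity.
    """
    empty = pd.DataFrame(columns=["snp", "trait", "pvalue"])
    if confounder_table is None or len(confounder_table) == 0:
        return harmonized, empty
    hits = confounder_table[
        confounder_table["pvalue"].astype(float) < p_threshold
    ]
    flagged = hits[hits["snp"].isin(harmonized.snp_ids)]
    if len(flagged) == 0:
        return harmonized, empty
    removed_ids = set(flagged["snp"])
    kept = [s for s in harmonized.snp_ids if s not in removed_ids]
    return (
        harmonized.subset(kept, dropped_reason="confounder_associated"),
        flagged.reset_index(drop=True),
    )
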