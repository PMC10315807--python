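"""GWAS summary-statistic containers, TSV readers/writers, and allele harmonization.

Two-sample MR consumes per-SNP association records (effect/other allele,
effect-allele frequency, beta, SE, p, N) for an exposure and an outcome
measured in non-overlapping cohorts.  Before any estimation, the outcome
effects must be expressed for the exposure's effect allele: swapped-allele
records are re-signed, palindromic (A/T, G/C) variants are dropped because
strand cannot be resolved from alleles alone, and allele-incompatible
records (e.g. A/G vs. A/C) are dropped.

The canonical on-disk dialect is a tab-separated table with columns
``snp, chr, pos, effect_allele, other_allele, eaf, beta, se, pval, n``.
A ``column_map`` adapts foreign headers (e.g. GWAS Catalog exports).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "VariantAssociation",
    "GwasTable",
    "HarmonizedSet",
    "LoadReport",
    "GwasFormatError",
    "GwasValidationError",
    "NoOverlapError",
    "read_gwas_table",
    "write_gwas_table",
    "harmonize_pair",
    "orient_effect",
    "is_palindromic",
    "CANONICAL_COLUMNS",
]

VALID_ALLELES = frozenset("ACGT")
_COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}

CANONICAL_COLUMNS = (
    "snp", "chr", "pos", "effect_allele", "other_allele",
    "eaf", "beta", "se", "pval", "n",
)


class GwasFormatError(ValueError):
    """A file does not conform to the expected delimited-text dialect."""


class GwasValidationError(ValueError):
    """A table violates a structural invariant (e.g. duplicate rsID)."""


class NoOverlapError(ValueError):
    """Exposure and outcome share no usable instruments."""


@dataclass(frozen=True)
class VariantAssociation:
    """One SNP-trait association record.

    ``beta`` is the per-allele effect of ``effect_allele`` (log-odds for a
    binary trait), ``eaf`` its frequency.  ``chrom``/``pos`` are carried for
    clumping windows but never used for joins (matching is by rsID).
    """

    snp_id: str
    effect_allele: str
    other_allele: str
    beta: float
    se: float
    pvalue: float
    n: float
    chrom: str | None = None
    pos: int | None = None
    eaf: float | None = None

    def __post_init__(self) -> None:
        if self.effect_allele not in VALID_ALLELES or self.other_allele not in VALID_ALLELES:
            raise GwasValidationError(
                f"{self.snp_id}: alleles must be single bases A/C/G/T, got "
                f"{self.effect_allele!r}/{self.other_allele!r}"
            )
        if self.effect_allele == self.other_allele:
            raise GwasValidationError(f"{self.snp_id}: identical alleles")
        if not (self.se > 0):
            raise GwasValidationError(f"{self.snp_id}: se must be > 0, got {self.se}")
        if not (0.0 <= self.pvalue <= 1.0):
            raise GwasValidationError(f"{self.snp_id}: p-value outside [0, 1]")
        if self.n < 1:
            raise GwasValidationError(f"{self.snp_id}: sample size < 1")
        if self.eaf is not None and not (0.0 < self.eaf < 1.0):
            raise GwasValidationError(f"{self.snp_id}: eaf must lie strictly in (0,1)")

    @property
    def palindromic(self) -> bool:
        return is_palindromic(self.effect_allele, self.other_allele)


def is_palindromic(a1: str, a2: str) -> bool:
    """A/T or G/C pairs: strand is unresolvable from alleles alone."""
    return _COMPLEMENT.get(a1) == a2


@dataclass
class LoadReport:
    """Bookkeeping for rows dropped while loading a summary-statistics file."""

    n_read: int = 0
    n_kept: int = 0
    dropped: list[tuple[str, str]] = field(default_factory=list)  # (snp or row label, reason)

    @property
    def n_dropped(self) -> int:
        return len(self.dropped)


@dataclass
class GwasTable:
    """A validated set of :class:`VariantAssociation` records for one trait."""

    trait_id: str
    trait_type: str  # "quantitative" | "binary"
    records: list[VariantAssociation]
    n_total: float | None = None
    n_cases: float | None = None
    load_report: LoadReport | None = None

    def __post_init__(self) -> None:
        if self.trait_type not in ("quantitative", "binary"):
            raise GwasValidationError(f"unknown trait_type {self.trait_type!r}")
        seen: set[str] = set()
        for rec in self.records:
            if rec.snp_id in seen:
                raise GwasValidationError(f"duplicate snp_id {rec.snp_id!r} in {self.trait_id}")
            seen.add(rec.snp_id)
        if self.n_cases is not None and self.n_total is not None and self.n_cases > self.n_total:
            raise GwasValidationError("n_cases exceeds n_total")
        self._index = {rec.snp_id: rec for rec in self.records}

    def __len__(self) -> int:
        return len(self.records)

    def __contains__(self, snp_id: str) -> bool:
        return snp_id in self._index

    def get(self, snp_id: str) -> VariantAssociation | None:
        return self._index.get(snp_id)

    @property
    def case_fraction(self) -> float | None:
        if self.n_cases is None or not self.n_total:
            return None
        return self.n_cases / self.n_total

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "snp": r.snp_id, "chr": r.chrom, "pos": r.pos,
                "effect_allele": r.effect_allele, "other_allele": r.other_allele,
                "eaf": r.eaf, "beta": r.beta, "se": r.se, "pval": r.pvalue, "n": r.n,
            }
            for r in self.records
        ]
        return pd.DataFrame(rows, columns=list(CANONICAL_COLUMNS))


def _coerce_optional(value) -> float | None:
    if value is None:
        return None
    if isinstance(value, float) and math.isnan(value):
        return None
    if isinstance(value, str) and value.strip() in ("", "NA", "NaN", "nan", "."):
        return None
    return float(value)


def read_gwas_table(
    path,
    trait_id: str,
    trait_type: str = "quantitative",
    column_map: Mapping[str, str] | None = None,
    n_total: float | None = None,
    n_cases: float | None = None,
    sep: str = "\t",
) -> GwasTable:
    """Load a delimited summary-statistics file into a :class:`GwasTable`.

    ``column_map`` maps canonical names to the file's header names, e.g.
    ``{"snp": "rsid", "pval": "p_value"}``.  Rows violating per-record
    invariants (non-SNP alleles, se <= 0, eaf outside (0,1), ...) are dropped
    and counted in ``table.load_report``; duplicate rsIDs raise.
    """
    df = pd.read_csv(path, sep=sep, dtype=str)
    cmap = dict(column_map or {})
    resolved = {canon: cmap.get(canon, canon) for canon in CANONICAL_COLUMNS}
    required = ("snp", "effect_allele", "other_allele", "beta", "se", "pval")
    for canon in required:
        if resolved[canon] not in df.columns:
            raise GwasFormatError(f"missing required column {resolved[canon]!r} in {path}")
    has_n = resolved["n"] in df.columns
    if not has_n and n_total is None:
        raise GwasFormatError("no per-SNP n column and no n_total supplied")

    report = LoadReport(n_read=len(df))
    records: list[VariantAssociation] = []
    for _, row in df.iterrows():
        snp = str(row[resolved["snp"]])
        try:
            n_val = _coerce_optional(row[resolved["n"]]) if has_n else None
            rec = VariantAssociation(
                snp_id=snp,
                effect_allele=str(row[resolved["effect_allele"]]).upper(),
                other_allele=str(row[resolved["other_allele"]]).upper(),
                beta=float(row[resolved["beta"]]),
                se=float(row[resolved["se"]]),
                pvalue=float(row[resolved["pval"]]),
                n=n_val if n_val is not None else float(n_total),
                chrom=(str(row[resolved["chr"]]) if resolved["chr"] in df.columns
                       and not pd.isna(row[resolved["chr"]]) else None),
                pos=(int(float(row[resolved["pos"]])) if resolved["pos"] in df.columns
                     and not pd.isna(row[resolved["pos"]]) else None),
                eaf=(_coerce_optional(row[resolved["eaf"]])
                     if resolved["eaf"] in df.columns else None),
            )
        except (GwasValidationError, ValueError) as exc:
            report.dropped.append((snp, str(exc)))
            continue
        records.append(rec)
    report.n_kept = len(records)
    return GwasTable(
        trait_id=trait_id, trait_type=trait_type, records=records,
        n_total=n_total, n_cases=n_cases, load_report=report,
    )


def write_gwas_table(table: GwasTable, path, sep: str = "\t") -> None:
    """Write a table in the canonical dialect (round-trips via :func:`read_gwas_table`)."""
    table.to_frame().to_csv(path, sep=sep, index=False)


def orient_effect(
    ref_ea: str, ref_oa: str, ea: str, oa: str,
    beta: float, eaf: float | None,
) -> tuple[float, float | None, str]:
    """Express an effect for the reference effect allele.

    Returns ``(beta, eaf, status)`` with status one of ``same`` (no change),
    ``swap`` (beta negated, eaf complemented), ``palindromic`` or
    ``incompatible_alleles``.  No strand inference is attempted: palindromic
    pairs are always flagged, and complement-strand matches count as
    incompatible.
    """
    if is_palindromic(ref_ea, ref_oa) or is_palindromic(ea, oa):
        return beta, eaf, "palindromic"
    if (ea, oa) == (ref_ea, ref_oa):
        return beta, eaf, "same"
    if (ea, oa) == (ref_oa, ref_ea):
        return -beta, (None if eaf is None else 1.0 - eaf), "swap"
    return beta, eaf, "incompatible_alleles"


@dataclass
class HarmonizedSet:
    """Exposure/outcome effect pairs on a common effect-allele orientation.

    ``df`` has one row per retained SNP with columns
    ``snp_id, effect_allele, other_allele, eaf, bx, sx, px, by, sy, py``
    where x = exposure, y = outcome.  ``dropped`` audits every requested SNP
    that did not survive, with a reason code.
    """

    exposure_id: str
    outcome_id: str
    df: pd.DataFrame
    dropped: list[tuple[str, str]] = field(default_factory=list)

    def __post_init__(self) -> None:
        if len(self.df):
            if not (self.df["sx"] > 0).all() or not (self.df["sy"] > 0).all():
                raise GwasValidationError("harmonized rows require sx > 0 and sy > 0")

    @property
    def n_snp(self) -> int:
        return len(self.df)

    @property
    def snp_ids(self) -> list[str]:
        return list(self.df["snp_id"])

    def arrays(self) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
        """(bx, sx, by, sy) as float arrays."""
        d = self.df
        return (d["bx"].to_numpy(float), d["sx"].to_numpy(float),
                d["by"].to_numpy(float), d["sy"].to_numpy(float))

    def subset(self, snp_ids: Iterable[str], dropped_reason: str | None = None) -> "HarmonizedSet":
        keep = set(snp_ids)
        removed = [s for s in self.df["snp_id"] if s not in keep]
        new_dropped = list(self.dropped)
        if dropped_reason is not None:
            new_dropped.extend((s, dropped_reason) for s in removed)
        return HarmonizedSet(
            exposure_id=self.exposure_id,
            outcome_id=self.outcome_id,
            df=self.df[self.df["snp_id"].isin(keep)].reset_index(drop=True),
            dropped=new_dropped,
        )

    def to_tsv(self, path, audit_path=None) -> None:
        self.df.to_csv(path, sep="\t", index=False)
        if audit_path is not None:
            pd.DataFrame(self.dropped, columns=["snp_id", "reason"]).to_csv(
                audit_path, sep="\t", index=False)


def harmonize_pair(
    exposure: GwasTable,
    outcome: GwasTable,
    snps: Sequence[str] | None = None,
) -> HarmonizedSet:
    """Match exposure and outcome records by rsID and align outcome effects
    to the exposure's effect allele.

    Swapped-allele outcome records have beta negated and eaf complemented;
    palindromic and allele-incompatible SNPs are dropped with their reason
    recorded, as are SNPs absent from the outcome.  Raises
    :class:`NoOverlapError` when nothing survives.
    """
    if snps is None:
        snps = [r.snp_id for r in exposure.records]
    rows = []
    dropped: list[tuple[str, str]] = []
    for snp in snps:
        ex = exposure.get(snp)
        if ex is None:
            raise KeyError(f"{snp} not present in exposure table {exposure.trait_id}")
        out = outcome.get(snp)
        if out is None:
            dropped.append((snp, "missing_in_outcome"))
            continue
        by, _eaf_out, status = orient_effect(
            ex.effect_allele, ex.other_allele,
            out.effect_allele, out.other_allele, out.beta, out.eaf,
        )
        if status in ("palindromic", "incompatible_alleles"):
            dropped.append((snp, status))
            continue
        rows.append({
            "snp_id": snp,
            "effect_allele": ex.effect_allele,
            "other_allele": ex.other_allele,
            "eaf": ex.eaf,
            "bx": ex.beta, "sx": ex.se, "px": ex.pvalue,
            "by": by, "sy": out.se, "py": out.pvalue,
        })
    if not rows:
        raise NoOverlapError(
            f"no overlapping instruments between {exposure.trait_id} and {outcome.trait_id}")
    df = pd.DataFrame(rows, columns=[
        "snp_id", "effect_allele", "other_allele", "eaf",
        "bx", "sx", "px", "by", "sy", "py",
    ])
    return HarmonizedSet(
        exposure_id=exposure.trait_id, outcome_id=outcome.trait_id,
        df=df, dropped=dropped,
    )
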