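"""Data model, validation and I/O for GWAS summary statistics.

Summary-statistics tables are tab-separated text with a header row,
UTF-8, ``NA`` for missing values; gzip compression is handled
transparently by file extension. Column names vary between consortia,
so reading goes through a *dialect*: a mapping from the canonical field
names used internally to the column headers of the file at hand. A
``generic`` dialect (SNP/CHR/BP/EA/OA/EAF/BETA/SE/P/N) ships with the
package; any mapping with the same keys may be supplied instead.

Coordinates are 1-based; genomic windows downstream are inclusive
center-to-center distances in kilobases, the usual GWAS convention.
"""

from __future__ import annotations

import dataclasses
import logging
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Iterator, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

VALID_ALLELES = frozenset({"A", "C", "G", "T"})

#: Smallest positive normal double; input p-values of exactly 0 are
#: floored here so that log/threshold operations stay well defined.
MIN_PVALUE = float(np.finfo(np.float64).tiny)


class ConfigurationError(ValueError):
    """A configuration problem: bad dialect, missing mandatory column."""


class InputError(ValueError):
    """An input-data problem: e.g. a file with zero valid rows."""


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class AssociationRecord:
    """One SNP's association with one trait.

    ``beta`` is the per-effect-allele estimate: log-odds for binary
    traits, SD units for quantitative ones. ``eaf`` (effect-allele
    frequency) and ``n`` may be missing (``None``).
    """

    snp_id: str
    chrom: str
    pos: int
    effect_allele: str
    other_allele: str
    beta: float
    se: float
    pvalue: float
    eaf: float | None = None
    n: int | None = None

    def __post_init__(self) -> None:
        if self.effect_allele not in VALID_ALLELES:
            raise ValueError(f"invalid effect allele {self.effect_allele!r}")
        if self.other_allele not in VALID_ALLELES:
            raise ValueError(f"invalid other allele {self.other_allele!r}")
        if self.effect_allele == self.other_allele:
            raise ValueError("effect and other allele must differ")
        if not (self.pos > 0):
            raise ValueError("position must be a positive 1-based integer")
        if not math.isfinite(self.beta):
            raise ValueError("beta must be finite")
        if not (math.isfinite(self.se) and self.se > 0):
            raise ValueError("nonpositive SE")
        if not (0.0 < self.pvalue <= 1.0):
            raise ValueError("p-value outside (0, 1]")
        if self.eaf is not None and not (0.0 <= self.eaf <= 1.0):
            raise ValueError("eaf outside [0, 1]")
        if self.n is not None and self.n <= 0:
            raise ValueError("n must be positive")


@dataclass(frozen=True)
class SumstatsTable:
    """An ordered collection of :class:`AssociationRecord` for one trait."""

    records: tuple[AssociationRecord, ...]
    trait_label: str = "trait"
    trait_type: str = "quantitative"

    def __post_init__(self) -> None:
        object.__setattr__(self, "records", tuple(self.records))
        if self.trait_type not in ("quantitative", "binary"):
            raise ValueError(f"unknown trait_type {self.trait_type!r}")
        ids = [r.snp_id for r in self.records]
        if len(ids) != len(set(ids)):
            seen: set[str] = set()
            dup = next(i for i in ids if i in seen or seen.add(i))
            raise ValueError(f"duplicate snp_id in table: {dup!r}")

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self) -> Iterator[AssociationRecord]:
        return iter(self.records)

    @property
    def snp_ids(self) -> tuple[str, ...]:
        return tuple(r.snp_id for r in self.records)

    def get(self, snp_id: str) -> AssociationRecord | None:
        return self._index().get(snp_id)

    def _index(self) -> dict[str, AssociationRecord]:
        return {r.snp_id: r for r in self.records}

    def replace_records(self, records: Iterable[AssociationRecord]) -> "SumstatsTable":
        return dataclasses.replace(self, records=tuple(records))

    def to_frame(self) -> pd.DataFrame:
        """Return the table as a pandas DataFrame with canonical columns."""
        return pd.DataFrame(
            {
                "snp_id": [r.snp_id for r in self.records],
                "chrom": [r.chrom for r in self.records],
                "pos": [r.pos for r in self.records],
                "effect_allele": [r.effect_allele for r in self.records],
                "other_allele": [r.other_allele for r in self.records],
                "eaf": [r.eaf for r in self.records],
                "beta": [r.beta for r in self.records],
                "se": [r.se for r in self.records],
                "pvalue": [r.pvalue for r in self.records],
                "n": [r.n for r in self.records],
            }
        )


@dataclass(frozen=True)
class HarmonizedInstrument:
    """One SNP with exposure and outcome effects on a shared effect allele."""

    snp_id: str
    effect_allele: str
    other_allele: str
    beta_exposure: float
    se_exposure: float
    beta_outcome: float
    se_outcome: float
    pvalue_exposure: float
    pvalue_outcome: float
    eaf_exposure: float | None = None

    def __post_init__(self) -> None:
        if self.se_exposure <= 0 or self.se_outcome <= 0:
            raise ValueError("standard errors must be positive")


# ---------------------------------------------------------------------------
# Dialects
# ---------------------------------------------------------------------------

GENERIC_DIALECT: Mapping[str, str] = {
    "snp_id": "SNP",
    "chrom": "CHR",
    "pos": "BP",
    "effect_allele": "EA",
    "other_allele": "OA",
    "eaf": "EAF",
    "beta": "BETA",
    "se": "SE",
    "pvalue": "P",
    "n": "N",
}

DIALECTS: Mapping[str, Mapping[str, str]] = {"generic": GENERIC_DIALECT}

_MANDATORY_FIELDS = (
    "snp_id",
    "chrom",
    "pos",
    "effect_allele",
    "other_allele",
    "beta",
    "se",
)
_OPTIONAL_FIELDS = ("eaf", "pvalue", "n")


def _resolve_dialect(dialect: str | Mapping[str, str]) -> Mapping[str, str]:
    if isinstance(dialect, str):
        try:
            return DIALECTS[dialect]
        except KeyError:
            raise ConfigurationError(f"unknown dialect {dialect!r}") from None
    missing = [f for f in _MANDATORY_FIELDS if f not in dialect]
    if missing:
        raise ConfigurationError(f"dialect lacks mappings for {missing}")
    return dialect


# ---------------------------------------------------------------------------
# Operations
# ---------------------------------------------------------------------------


def pvalue_from_z(beta: float, se: float) -> float:
    """Two-sided normal p-value for an estimate ``beta`` with SE ``se``.

    Returns ``2 * (1 - Phi(|beta/se|))``, floored at the smallest
    positive normal double so the result stays in (0, 1].
    """
    if se <= 0:
        raise ValueError("se must be positive")
    p = 2.0 * stats.norm.sf(abs(beta / se))
    return float(max(p, MIN_PVALUE))


def read_sumstats(
    path: str | Path,
    dialect: str | Mapping[str, str] = "generic",
    trait_label: str | None = None,
    trait_type: str = "quantitative",
) -> SumstatsTable:
    """Read a summary-statistics TSV into a validated :class:`SumstatsTable`.

    Rows failing validation are dropped with a logged reason; alleles
    are upper-cased; p-values of 0 are floored to the smallest positive
    normal double; duplicate ``snp_id`` rows keep the smallest p-value.
    If the file lacks a p-value column, p is computed from beta/SE.

    Raises :class:`ConfigurationError` if a mandatory mapped column is
    absent, and :class:`InputError` if no valid row remains.
    """
    path = Path(path)
    mapping = _resolve_dialect(dialect)
    df = pd.read_csv(path, sep="\t", dtype=str, na_values=["NA"], keep_default_na=True)
    for field in _MANDATORY_FIELDS:
        if mapping[field] not in df.columns:
            raise ConfigurationError(
                f"mandatory column {mapping[field]!r} (field {field!r}) "
                f"missing from {path}"
            )
    have_pvalue = "pvalue" in mapping and mapping["pvalue"] in df.columns
    have_eaf = "eaf" in mapping and mapping["eaf"] in df.columns
    have_n = "n" in mapping and mapping["n"] in df.columns

    records: list[AssociationRecord] = []
    drop_reasons: dict[str, int] = {}
    n_floored = 0
    for row in df.itertuples(index=False):
        row_d = dict(zip(df.columns, row))
        try:
            beta = float(row_d[mapping["beta"]])
            se = float(row_d[mapping["se"]])
            if have_pvalue and not pd.isna(row_d[mapping["pvalue"]]):
                pvalue = float(row_d[mapping["pvalue"]])
                if pvalue == 0.0:
                    pvalue = MIN_PVALUE
                    n_floored += 1
            else:
                pvalue = pvalue_from_z(beta, se) if se > 0 else float("nan")
            eaf_raw = row_d[mapping["eaf"]] if have_eaf else None
            n_raw = row_d[mapping["n"]] if have_n else None
            rec = AssociationRecord(
                snp_id=str(row_d[mapping["snp_id"]]),
                chrom=str(row_d[mapping["chrom"]]),
                pos=int(float(row_d[mapping["pos"]])),
                effect_allele=str(row_d[mapping["effect_allele"]]).upper(),
                other_allele=str(row_d[mapping["other_allele"]]).upper(),
                beta=beta,
                se=se,
                pvalue=pvalue,
                eaf=None if eaf_raw is None or pd.isna(eaf_raw) else float(eaf_raw),
                n=None if n_raw is None or pd.isna(n_raw) else int(float(n_raw)),
            )
        except (ValueError, TypeError) as exc:
            reason = str(exc) or exc.__class__.__name__
            drop_reasons[reason] = drop_reasons.get(reason, 0) + 1
            continue
        records.append(rec)

    if n_floored:
        logger.info("%s: floored %d zero p-values to %.3e", path, n_floored, MIN_PVALUE)
    for reason, count in drop_reasons.items():
        logger.info("%s: dropped %d row(s): %s", path, count, reason)

    # duplicate snp_ids: keep the smallest p-value, preserve first position
    by_id: dict[str, AssociationRecord] = {}
    order: list[str] = []
    n_dup = 0
    for rec in records:
        prev = by_id.get(rec.snp_id)
        if prev is None:
            by_id[rec.snp_id] = rec
            order.append(rec.snp_id)
        else:
            n_dup += 1
            if rec.pvalue < prev.pvalue:
                by_id[rec.snp_id] = rec
    if n_dup:
        logger.info("%s: dropped %d duplicate snp_id row(s), kept smallest p", path, n_dup)
    records = [by_id[i] for i in order]

    if not records:
        raise InputError(f"no valid summary-statistics rows in {path}")
    return SumstatsTable(
        records=tuple(records),
        trait_label=trait_label if trait_label is not None else path.stem,
        trait_type=trait_type,
    )


def write_sumstats(table: SumstatsTable, path: str | Path) -> None:
    """Write a table as generic-dialect TSV; lossless for re-reading.

    Floats are serialized with ``repr`` (shortest round-trip form) and
    missing values as ``NA``.
    """
    path = Path(path)
    rows = []
    for r in table.records:
        rows.append(
            {
                "SNP": r.snp_id,
                "CHR": r.chrom,
                "BP": r.pos,
                "EA": r.effect_allele,
                "OA": r.other_allele,
                "EAF": "NA" if r.eaf is None else repr(r.eaf),
                "BETA": repr(r.beta),
                "SE": repr(r.se),
                "P": repr(r.pvalue),
                "N": "NA" if r.n is None else r.n,
            }
        )
    df = pd.DataFrame(rows, columns=list(GENERIC_DIALECT.values()))
    df.to_csv(path, sep="\t", index=False)


_HARMONIZED_COLUMNS = (
    "snp_id",
    "effect_allele",
    "other_allele",
    "eaf_exposure",
    "beta_exposure",
    "se_exposure",
    "pvalue_exposure",
    "beta_outcome",
    "se_outcome",
    "pvalue_outcome",
)


def write_harmonized(instruments: Sequence[HarmonizedInstrument], path: str | Path) -> None:
    """Serialize harmonized instruments with the fixed column order."""
    rows = []
    for h in instruments:
        rows.append(
            {
                "snp_id": h.snp_id,
                "effect_allele": h.effect_allele,
                "other_allele": h.other_allele,
                "eaf_exposure": "NA" if h.eaf_exposure is None else repr(h.eaf_exposure),
                "beta_exposure": repr(h.beta_exposure),
                "se_exposure": repr(h.se_exposure),
                "pvalue_exposure": repr(h.pvalue_exposure),
                "beta_outcome": repr(h.beta_outcome),
                "se_outcome": repr(h.se_outcome),
                "pvalue_outcome": repr(h.pvalue_outcome),
            }
        )
    pd.DataFrame(rows, columns=list(_HARMONIZED_COLUMNS)).to_csv(
        Path(path), sep="\t", index=False
    )


def read_harmonized(path: str | Path) -> list[HarmonizedInstrument]:
    """Read a harmonized-instrument TSV written by :func:`write_harmonized`."""
    df = pd.read_csv(path, sep="\t", dtype=str, na_values=["NA"])
    missing = [c for c in _HARMONIZED_COLUMNS if c not in df.columns]
    if missing:
        raise ConfigurationError(f"harmonized table {path} lacks columns {missing}")
    out = []
    for row in df.itertuples(index=False):
        d = dict(zip(df.columns, row))
        out.append(
            HarmonizedInstrument(
                snp_id=str(d["snp_id"]),
                effect_allele=str(d["effect_allele"]),
                other_allele=str(d["other_allele"]),
                eaf_exposure=None if pd.isna(d["eaf_exposure"]) else float(d["eaf_exposure"]),
                beta_exposure=float(d["beta_exposure"]),
                se_exposure=float(d["se_exposure"]),
                pvalue_exposure=float(d["pvalue_exposure"]),
                beta_outcome=float(d["beta_outcome"]),
                se_outcome=float(d["se_outcome"]),
                pvalue_outcome=float(d["pvalue_outcome"]),
            )
        )
    return out
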