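"""Selection of independent, strong, exposure-specific instruments.

The selection pipeline applied to an exposure table is:

1. genome-wide significance filter (strict ``p < p_threshold``);
2. greedy LD clumping against a pairwise r-squared matrix, keeping the
   most significant SNP of every correlated group within a genomic
   window;
3. instrument-strength screen with the per-SNP F statistic
   ``(beta/se)^2``, keeping ``F > f_min`` (F > 10 is the conventional
   "strong instrument" bar);
4. exclusion of instruments already associated with the outcome
   (``p < outcome_p_exclude``), which would violate the exclusion
   restriction;
5. optional removal of a user-supplied SNP list (e.g. variants known to
   associate with confounders of the exposure-outcome pair).

Every filter only removes rows and never modifies surviving records, so
the pipeline is idempotent and order-stable.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd

from mrpipe.sumstats import AssociationRecord, SumstatsTable

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class LDMatrix:
    """Pairwise r-squared among a set of SNPs, with genomic positions.

    ``r2`` is symmetric with unit diagonal; ``chrom``/``pos`` give each
    SNP's location for the clumping window predicate.
    """

    snp_ids: tuple[str, ...]
    chrom: tuple[str, ...]
    pos: tuple[int, ...]
    r2: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "snp_ids", tuple(self.snp_ids))
        object.__setattr__(self, "chrom", tuple(str(c) for c in self.chrom))
        object.__setattr__(self, "pos", tuple(int(p) for p in self.pos))
        r2 = np.asarray(self.r2, dtype=float)
        object.__setattr__(self, "r2", r2)
        k = len(self.snp_ids)
        if not (len(self.chrom) == len(self.pos) == k):
            raise ValueError("snp_ids, chrom and pos must have equal length")
        if r2.shape != (k, k):
            raise ValueError(f"r2 must be {k}x{k}, got {r2.shape}")
        if len(set(self.snp_ids)) != k:
            raise ValueError("duplicate snp_id in LD matrix")
        if not np.allclose(r2, r2.T, atol=1e-12):
            raise ValueError("r2 matrix is not symmetric")
        if not np.allclose(np.diag(r2), 1.0, atol=1e-12):
            raise ValueError("r2 diagonal must be 1")
        if r2.min() < -1e-12 or r2.max() > 1 + 1e-12:
            raise ValueError("r2 entries must lie in [0, 1]")

    def __len__(self) -> int:
        return len(self.snp_ids)

    @property
    def index(self) -> dict[str, int]:
        return {s: i for i, s in enumerate(self.snp_ids)}

    def r2_between(self, a: str, b: str) -> float:
        idx = self.index
        return float(self.r2[idx[a], idx[b]])

    @classmethod
    def identity(cls, table: SumstatsTable) -> "LDMatrix":
        """LD matrix asserting pairwise independence of a table's SNPs."""
        k = len(table)
        return cls(
            snp_ids=table.snp_ids,
            chrom=tuple(r.chrom for r in table),
            pos=tuple(r.pos for r in table),
            r2=np.eye(k),
        )

    def to_files(self, info_path: str | Path, matrix_path: str | Path) -> None:
        """Write the SNP-info TSV and the square r2 matrix TSV."""
        pd.DataFrame(
            {"snp_id": self.snp_ids, "chrom": self.chrom, "pos": self.pos}
        ).to_csv(Path(info_path), sep="\t", index=False)
        pd.DataFrame(self.r2, index=self.snp_ids, columns=self.snp_ids).to_csv(
            Path(matrix_path), sep="\t", index_label="snp_id"
        )

    @classmethod
    def from_files(cls, info_path: str | Path, matrix_path: str | Path) -> "LDMatrix":
        info = pd.read_csv(Path(info_path), sep="\t", dtype={"snp_id": str, "chrom": str})
        mat = pd.read_csv(Path(matrix_path), sep="\t", index_col=0)
        ids = tuple(info["snp_id"])
        if tuple(mat.index) != ids or tuple(mat.columns) != ids:
            raise ValueError("LD matrix row/column order does not match SNP info")
        return cls(
            snp_ids=ids,
            chrom=tuple(info["chrom"]),
            pos=tuple(info["pos"]),
            r2=mat.to_numpy(dtype=float),
        )


@dataclass(frozen=True)
class SelectionConfig:
    """Thresholds for the instrument-selection pipeline.

    The defaults suit a large-GWAS exposure (hundreds of genome-wide
    hits): a stringent significance threshold of 5e-9 with tight
    clumping (r2 < 0.001 within 1,000 kb). For modest-scale exposure
    GWASs use :meth:`relaxed`: 5e-8 with r2 < 0.1 within 500 kb.
    """

    p_threshold: float = 5e-9
    clump_r2: float = 0.001
    clump_window_kb: int = 1000
    f_min: float = 10.0
    outcome_p_exclude: float = 1e-5

    def __post_init__(self) -> None:
        if not (0 < self.p_threshold < 1):
            raise ValueError("p_threshold must be in (0, 1)")
        if not (0 < self.clump_r2 < 1):
            raise ValueError("clump_r2 must be in (0, 1)")
        if self.clump_window_kb <= 0:
            raise ValueError("clump_window_kb must be positive")
        if self.f_min <= 0:
            raise ValueError("f_min must be positive")
        if not (0 < self.outcome_p_exclude < 1):
            raise ValueError("outcome_p_exclude must be in (0, 1)")

    @classmethod
    def relaxed(cls) -> "SelectionConfig":
        """Preset for modest-scale exposure GWASs (e.g. cytometry panels)."""
        return cls(p_threshold=5e-8, clump_r2=0.1, clump_window_kb=500)


def filter_significant(table: SumstatsTable, p_threshold: float) -> SumstatsTable:
    """Keep records with ``pvalue < p_threshold`` (strict), order preserved."""
    if not (0 < p_threshold < 1):
        raise ValueError("p_threshold must be in (0, 1)")
    kept = [r for r in table.records if r.pvalue < p_threshold]
    logger.info(
        "%s: significance filter p<%g kept %d of %d SNPs",
        table.trait_label, p_threshold, len(kept), len(table),
    )
    return table.replace_records(kept)


def _clump_sort_key(r: AssociationRecord):
    # deterministic tie-break when p-values are equal
    return (r.pvalue, r.chrom, r.pos, r.snp_id)


def ld_clump(
    table: SumstatsTable,
    ld: LDMatrix,
    r2_threshold: float,
    window_kb: int,
) -> SumstatsTable:
    """Greedy LD clumping: repeatedly promote the most significant
    remaining SNP to index SNP and discard correlated neighbours.

    A neighbour is discarded when it lies on the index SNP's chromosome
    within ``window_kb`` (inclusive center-to-center distance) and its
    r-squared with the index SNP is >= ``r2_threshold``. Returns the
    index SNPs sorted by ascending p-value. Every table SNP must be
    present in ``ld``.
    """
    if not (0 < r2_threshold < 1):
        raise ValueError("r2_threshold must be in (0, 1)")
    if window_kb <= 0:
        raise ValueError("window_kb must be positive")
    idx = ld.index
    for r in table.records:
        if r.snp_id not in idx:
            raise KeyError(f"SNP {r.snp_id!r} absent from LD matrix")

    window_bp = int(window_kb) * 1000
    remaining = sorted(table.records, key=_clump_sort_key)
    kept: list[AssociationRecord] = []
    while remaining:
        index_snp = remaining.pop(0)
        kept.append(index_snp)
        i = idx[index_snp.snp_id]
        survivors = []
        for r in remaining:
            same_chrom = r.chrom == index_snp.chrom
            in_window = same_chrom and abs(r.pos - index_snp.pos) <= window_bp
            if in_window and ld.r2[i, idx[r.snp_id]] >= r2_threshold:
                logger.debug(
                    "clump: %s removed (r2=%.4g with index %s)",
                    r.snp_id, ld.r2[i, idx[r.snp_id]], index_snp.snp_id,
                )
            else:
                survivors.append(r)
        remaining = survivors
    logger.info(
        "%s: clumping (r2<%g, %d kb) kept %d of %d SNPs",
        table.trait_label, r2_threshold, window_kb, len(kept), len(table),
    )
    return table.replace_records(kept)


def f_statistic(record: AssociationRecord) -> float:
    """Per-SNP instrument-strength F statistic, ``(beta/se)^2``."""
    if record.se <= 0:
        raise ValueError("se must be positive")
    return (record.beta / record.se) ** 2


def filter_strong(table: SumstatsTable, f_min: float = 10.0) -> SumstatsTable:
    """Keep records with F statistic strictly above ``f_min``."""
    if f_min <= 0:
        raise ValueError("f_min must be positive")
    kept = [r for r in table.records if f_statistic(r) > f_min]
    logger.info(
        "%s: F>%g screen kept %d of %d SNPs",
        table.trait_label, f_min, len(kept), len(table),
    )
    return table.replace_records(kept)


def drop_outcome_associated(
    instruments: SumstatsTable,
    outcome: SumstatsTable,
    p_exclude: float = 1e-5,
) -> SumstatsTable:
    """Remove instruments already associated with the outcome.

    An instrument is removed when its outcome record has
    ``pvalue < p_exclude`` (a variant with its own outcome association
    is a likely exclusion-restriction violation), or when it is absent
    from the outcome table (no LD-proxy search is attempted).
    """
    if not (0 < p_exclude < 1):
        raise ValueError("p_exclude must be in (0, 1)")
    outcome_index = outcome._index()
    kept: list[AssociationRecord] = []
    n_assoc = n_missing = 0
    for r in instruments.records:
        out = outcome_index.get(r.snp_id)
        if out is None:
            n_missing += 1
            logger.debug("%s: not found in outcome, removed", r.snp_id)
        elif out.pvalue < p_exclude:
            n_assoc += 1
            logger.debug("%s: outcome p=%.3g < %g, removed", r.snp_id, out.pvalue, p_exclude)
        else:
            kept.append(r)
    logger.info(
        "%s: outcome-overlap screen removed %d outcome-associated and %d "
        "not-found SNPs (%d kept)",
        instruments.trait_label, n_assoc, n_missing, len(kept),
    )
    return instruments.replace_records(kept)


def drop_listed(
    instruments: SumstatsTable,
    exclusion_ids: Iterable[str],
    label: str = "exclusion list",
) -> SumstatsTable:
    """Remove instruments whose snp_id is in ``exclusion_ids``.

    Typically used for variants a confounder lookup flagged. Unknown
    ids are ignored with a log note.
    """
    exclusion = set(exclusion_ids)
    unknown = exclusion - set(instruments.snp_ids)
    if unknown:
        logger.info("%s: %d listed id(s) not in table, ignored", label, len(unknown))
    kept = [r for r in instruments.records if r.snp_id not in exclusion]
    logger.info(
        "%s: removed %d of %d instruments (%s)",
        instruments.trait_label, len(instruments) - len(kept), len(instruments), label,
    )
    return instruments.replace_records(kept)


def read_exclusion_list(path: str | Path) -> set[str]:
    """Read a plain-text exclusion list, one snp_id per line."""
    ids = set()
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if line and not line.startswith("#"):
            ids.add(line)
    return ids
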