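"""Align exposure and outcome effects onto a common effect allele.

Two GWASs may report the same SNP with the roles of the two alleles
swapped, or coded on opposite strands. Harmonization rewrites every
outcome record into the exposure's allele frame:

* same orientation — copied through;
* alleles swapped (or complement-swapped) — outcome beta negated, its
  allele frequency reflected;
* allele sets that differ even after strand complementing — dropped as
  incompatible;
* palindromic SNPs (A/T or C/G) — strand cannot be resolved from the
  allele labels. Outside an ambiguity window around 0.5 the effect
  allele is identifiable from its frequency, so the SNP is retained and
  oriented by frequency agreement when the outcome reports a frequency;
  inside the window (default 0.42-0.58), or with a missing exposure
  frequency, the SNP is dropped as ambiguous.

Every input SNP appears exactly once in the action log of the returned
report, so the counts always sum to the input size.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import pandas as pd

from mrpipe.sumstats import (
    VALID_ALLELES,
    AssociationRecord,
    HarmonizedInstrument,
    SumstatsTable,
)

logger = logging.getLogger(__name__)

_COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}


@dataclass(frozen=True)
class HarmonizeConfig:
    """Palindromic ambiguity window and the all-drop fallback.

    ``palindromic_eaf_low``/``high`` bound the symmetric frequency
    window inside which a palindromic SNP's strand cannot be inferred;
    ``drop_all_palindromic=True`` discards every palindromic SNP
    regardless of frequency.
    """

    palindromic_eaf_low: float = 0.42
    palindromic_eaf_high: float = 0.58
    drop_all_palindromic: bool = False

    def __post_init__(self) -> None:
        if not (0.0 < self.palindromic_eaf_low < self.palindromic_eaf_high < 1.0):
            raise ValueError("require 0 < low < high < 1")
        if abs(self.palindromic_eaf_low + self.palindromic_eaf_high - 1.0) > 1e-12:
            raise ValueError("ambiguity window must be symmetric about 0.5")


@dataclass(frozen=True)
class HarmonizeAction:
    snp_id: str
    action: str  # kept | flipped | dropped
    reason: str  # "" for kept/flipped, else drop reason


@dataclass(frozen=True)
class HarmonizeReport:
    """Per-SNP action log plus summary counts."""

    actions: tuple[HarmonizeAction, ...]

    def _count(self, action: str, reason: str | None = None) -> int:
        return sum(
            1
            for a in self.actions
            if a.action == action and (reason is None or a.reason == reason)
        )

    @property
    def n_input(self) -> int:
        return len(self.actions)

    @property
    def n_kept(self) -> int:
        return self._count("kept")

    @property
    def n_flipped(self) -> int:
        return self._count("flipped")

    @property
    def n_dropped_palindromic(self) -> int:
        return sum(
            1
            for a in self.actions
            if a.action == "dropped" and a.reason.startswith("palindromic")
        )

    @property
    def n_dropped_incompatible(self) -> int:
        return self._count("dropped", "incompatible_alleles")

    @property
    def n_dropped_missing(self) -> int:
        return self._count("dropped", "not_in_outcome")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "snp_id": [a.snp_id for a in self.actions],
                "action": [a.action for a in self.actions],
                "reason": [a.reason for a in self.actions],
            }
        )

    def write(self, path: str | Path) -> None:
        self.to_frame().to_csv(Path(path), sep="\t", index=False)


def is_palindromic(a1: str, a2: str) -> bool:
    """True iff the allele pair is strand-ambiguous ({A,T} or {C,G})."""
    if a1 not in VALID_ALLELES or a2 not in VALID_ALLELES:
        raise ValueError(f"invalid allele pair ({a1!r}, {a2!r})")
    return {a1, a2} in ({"A", "T"}, {"C", "G"})


def _harmonize_one(
    exp: AssociationRecord,
    out: AssociationRecord,
    cfg: HarmonizeConfig,
) -> tuple[HarmonizedInstrument | None, HarmonizeAction]:
    ea, oa = exp.effect_allele, exp.other_allele
    out_pair = (out.effect_allele, out.other_allele)
    palindromic = is_palindromic(ea, oa)

    if palindromic:
        if out_pair not in ((ea, oa), (oa, ea)):
            return None, HarmonizeAction(exp.snp_id, "dropped", "incompatible_alleles")
        if cfg.drop_all_palindromic:
            return None, HarmonizeAction(exp.snp_id, "dropped", "palindromic")
        if exp.eaf is None:
            return None, HarmonizeAction(exp.snp_id, "dropped", "palindromic_missing_eaf")
        if cfg.palindromic_eaf_low < exp.eaf < cfg.palindromic_eaf_high:
            return None, HarmonizeAction(
                exp.snp_id, "dropped", "palindromic_intermediate_eaf"
            )
        # align labels first, then let frequency agreement decide strand
        if out_pair == (ea, oa):
            beta_out, eaf_out = out.beta, out.eaf
        else:
            beta_out = -out.beta
            eaf_out = None if out.eaf is None else 1.0 - out.eaf
        flipped = out_pair != (ea, oa)
        if eaf_out is not None and (exp.eaf < 0.5) != (eaf_out < 0.5):
            beta_out = -beta_out
            flipped = not flipped
        action = "flipped" if flipped else "kept"
    else:
        comp = (_COMPLEMENT[ea], _COMPLEMENT[oa])
        if out_pair in ((ea, oa), comp):
            beta_out = out.beta
            action = "kept"
        elif out_pair in ((oa, ea), (comp[1], comp[0])):
            beta_out = -out.beta
            action = "flipped"
        else:
            return None, HarmonizeAction(exp.snp_id, "dropped", "incompatible_alleles")

    inst = HarmonizedInstrument(
        snp_id=exp.snp_id,
        effect_allele=ea,
        other_allele=oa,
        beta_exposure=exp.beta,
        se_exposure=exp.se,
        beta_outcome=beta_out,
        se_outcome=out.se,
        pvalue_exposure=exp.pvalue,
        pvalue_outcome=out.pvalue,
        eaf_exposure=exp.eaf,
    )
    return inst, HarmonizeAction(exp.snp_id, action, "")


def harmonize(
    exposure: SumstatsTable,
    outcome: SumstatsTable,
    cfg: HarmonizeConfig | None = None,
) -> tuple[list[HarmonizedInstrument], HarmonizeReport]:
    """Harmonize every exposure SNP against the outcome table.

    Returns the harmonized instruments (exposure order preserved) and
    an action log accounting for every input SNP. Instruments missing
    from the outcome table are dropped with reason ``not_in_outcome``
    (they should normally have been removed upstream).
    """
    cfg = cfg or HarmonizeConfig()
    outcome_index = outcome._index()
    instruments: list[HarmonizedInstrument] = []
    actions: list[HarmonizeAction] = []
    for exp in exposure.records:
        out = outcome_index.get(exp.snp_id)
        if out is None:
            actions.append(HarmonizeAction(exp.snp_id, "dropped", "not_in_outcome"))
            continue
        inst, action = _harmonize_one(exp, out, cfg)
        actions.append(action)
        if inst is not None:
            instruments.append(inst)
    report = HarmonizeReport(actions=tuple(actions))
    logger.info(
        "%s vs %s: harmonized %d SNPs (%d as-is, %d flipped), dropped %d "
        "palindromic, %d incompatible, %d missing",
        exposure.trait_label, outcome.trait_label,
        report.n_kept + report.n_flipped, report.n_kept, report.n_flipped,
        report.n_dropped_palindromic, report.n_dropped_incompatible,
        report.n_dropped_missing,
    )
    return instruments, report
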