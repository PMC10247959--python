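"""Synthetic two-sample GWAS generator with known causal truth.

The generating model is the standard summary-data MR data model: each
SNP *j* has a true effect ``gamma_j`` on the exposure and a direct
(pleiotropic) effect ``alpha_j`` on the outcome, and the observed
estimates are

    bx_j ~ Normal(gamma_j, se_exposure^2)
    by_j ~ Normal(beta_causal * gamma_j + alpha_j, se_outcome^2)

with exposure and outcome draws independent (the two-sample design).
``alpha_j`` is zero (no pleiotropy), centred at zero (balanced, InSIDE
holds) or shifted (directional). Truth is expressed in the frame of
the exposure-increasing allele (``gamma_j >= 0``); the emitted tables
re-code each SNP's effect allele at random, independently for the two
GWASs, so reported signs are symmetric and harmonization is genuinely
exercised. LD is encoded directly as a block-diagonal r-squared matrix
(clumping consumes only r-squared, so no genotypes are simulated).

Defaults mimic a well-powered blood-trait exposure GWAS (per-SNP
sampling SE about 0.002 SD units, as for n around 5e5) against a
biobank-scale binary outcome (log-odds SE about 0.003), with true
instrument effects of a few hundredths of an SD.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

from mrpipe.sumstats import AssociationRecord, SumstatsTable, pvalue_from_z
from mrpipe.instruments import LDMatrix, SelectionConfig
from mrpipe.harmonize import HarmonizeConfig, harmonize
from mrpipe.estimators import egger, ivw, weighted_median

logger = logging.getLogger(__name__)

_NONPALINDROMIC_PAIRS = (("A", "G"), ("A", "C"), ("T", "G"), ("T", "C"))
_PALINDROMIC_PAIRS = (("A", "T"), ("C", "G"))

#: spacing of SNPs inside one LD block (bp); well inside a 500-kb window
_WITHIN_BLOCK_BP = 10_000
#: spacing between blocks (bp); beyond any default clumping window
_BETWEEN_BLOCK_BP = 10_000_000


@dataclass(frozen=True)
class SimConfig:
    """Generating parameters for one synthetic exposure/outcome pair.

    ``gamma_sd`` sets the spread of true SNP-exposure effects (SD units
    per allele); ``se_exposure``/``se_outcome`` are the per-SNP sampling
    SEs of the two GWASs (scalar or per-SNP vectors), conceptually
    proportional to 1/sqrt(n). ``ld_blocks`` lists (block size,
    within-block r2) pairs; SNPs not covered by a block are mutually
    independent. Setting an SE to 0 yields the noise-free limit where
    every Wald ratio equals ``beta_causal`` exactly (the emitted SE
    column is a tiny positive placeholder).
    """

    n_snp: int = 50
    beta_causal: float = 0.0
    gamma_sd: float = 0.05
    se_exposure: float | Sequence[float] = 0.002
    se_outcome: float | Sequence[float] = 0.003
    pleiotropy_mode: str = "none"  # none | balanced | directional
    pleiotropy_sd: float = 0.0
    pleiotropy_mean: float = 0.0
    prop_palindromic: float = 0.2
    ld_blocks: tuple[tuple[int, float], ...] = ()
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_snp < 1:
            raise ValueError("n_snp must be >= 1")
        if self.gamma_sd <= 0:
            raise ValueError("gamma_sd must be positive")
        if self.pleiotropy_mode not in ("none", "balanced", "directional"):
            raise ValueError(f"unknown pleiotropy_mode {self.pleiotropy_mode!r}")
        if self.pleiotropy_sd < 0:
            raise ValueError("pleiotropy_sd must be >= 0")
        if self.pleiotropy_mode == "balanced" and self.pleiotropy_mean != 0:
            raise ValueError("balanced pleiotropy requires pleiotropy_mean = 0")
        if not (0.0 <= self.prop_palindromic <= 1.0):
            raise ValueError("prop_palindromic must be in [0, 1]")
        for size, r2 in self.ld_blocks:
            if size < 1 or not (0.0 <= r2 <= 1.0):
                raise ValueError("ld_blocks entries must be (size>=1, r2 in [0,1])")
        if sum(size for size, _ in self.ld_blocks) > self.n_snp:
            raise ValueError("ld_blocks cover more SNPs than n_snp")
        for name in ("se_exposure", "se_outcome"):
            v = np.atleast_1d(np.asarray(getattr(self, name), dtype=float))
            if np.any(v < 0):
                raise ValueError(f"{name} must be >= 0")
            if v.size not in (1, self.n_snp):
                raise ValueError(f"{name} must be scalar or length n_snp")


@dataclass(frozen=True)
class SimTruth:
    """Generating truth, in the exposure-increasing-allele frame."""

    beta_causal: float
    gamma: tuple[float, ...]
    alpha: tuple[float, ...]
    seed: int

    def write(self, path: str | Path) -> None:
        pd.DataFrame(
            {
                "snp": [f"rs{i + 1:06d}" for i in range(len(self.gamma))],
                "gamma": self.gamma,
                "alpha": self.alpha,
                "beta_causal": self.beta_causal,
                "seed": self.seed,
            }
        ).to_csv(Path(path), sep="\t", index=False)


def load_sim_config(path: str | Path) -> SimConfig:
    """Load a simulation scenario from a plain-text key-value (YAML) file.

    Keys mirror :class:`SimConfig` fields; ``ld_blocks`` entries are
    ``[size, r2]`` pairs.
    """
    raw = yaml.safe_load(Path(path).read_text()) or {}
    if "ld_blocks" in raw:
        raw["ld_blocks"] = tuple((int(s), float(r)) for s, r in raw["ld_blocks"])
    return SimConfig(**raw)


def _per_snp(value, n: int) -> np.ndarray:
    v = np.atleast_1d(np.asarray(value, dtype=float))
    return np.full(n, v[0]) if v.size == 1 else v.copy()


def _block_layout(cfg: SimConfig) -> tuple[list[str], list[int], np.ndarray]:
    """Chromosomes, positions and the block-diagonal r2 matrix."""
    sizes = [size for size, _ in cfg.ld_blocks]
    r2s = [r2 for _, r2 in cfg.ld_blocks]
    n_left = cfg.n_snp - sum(sizes)
    sizes += [1] * n_left
    r2s += [0.0] * n_left

    chroms: list[str] = []
    positions: list[int] = []
    r2 = np.eye(cfg.n_snp)
    i = 0
    chrom_cycle = [str(c) for c in range(1, 23)]
    for b, (size, block_r2) in enumerate(zip(sizes, r2s)):
        chrom = chrom_cycle[b % len(chrom_cycle)]
        base = 1_000_000 + (b // len(chrom_cycle)) * _BETWEEN_BLOCK_BP
        for k in range(size):
            chroms.append(chrom)
            positions.append(base + k * _WITHIN_BLOCK_BP)
        if size > 1 and block_r2 > 0:
            r2[i : i + size, i : i + size] = block_r2
            np.fill_diagonal(r2[i : i + size, i : i + size], 1.0)
        i += size
    return chroms, positions, r2


def simulate_pair(
    cfg: SimConfig,
) -> tuple[SumstatsTable, SumstatsTable, LDMatrix, SimTruth]:
    """Generate one exposure/outcome summary-statistics pair.

    Deterministic given ``cfg`` (including its seed). Returns the two
    tables, the block-diagonal LD matrix, and the exact generating
    truth for recovery tests.
    """
    rng = np.random.default_rng(np.random.SeedSequence(cfg.seed))
    n = cfg.n_snp

    # truth in the exposure-increasing-allele frame
    gamma = np.abs(rng.normal(0.0, cfg.gamma_sd, size=n))
    gamma = np.maximum(gamma, 1e-12)  # keep Wald ratios defined in edge draws
    if cfg.pleiotropy_mode == "none":
        alpha = np.zeros(n)
    else:
        mean = cfg.pleiotropy_mean if cfg.pleiotropy_mode == "directional" else 0.0
        alpha = rng.normal(mean, cfg.pleiotropy_sd, size=n)

    se_x = _per_snp(cfg.se_exposure, n)
    se_y = _per_snp(cfg.se_outcome, n)
    noise_x = np.where(se_x > 0, rng.normal(0.0, 1.0, size=n) * se_x, 0.0)
    noise_y = np.where(se_y > 0, rng.normal(0.0, 1.0, size=n) * se_y, 0.0)
    bx = gamma + noise_x
    by = cfg.beta_causal * gamma + alpha + noise_y
    # a strictly positive SE is required downstream; the placeholder in the
    # noise-free limit is small enough that p-values degenerate as expected
    se_x_out = np.where(se_x > 0, se_x, 1e-8)
    se_y_out = np.where(se_y > 0, se_y, 1e-8)

    # allele assignment and per-GWAS coding
    n_pal = int(round(cfg.prop_palindromic * n))
    pal_idx = set(rng.choice(n, size=n_pal, replace=False).tolist())
    eaf = rng.uniform(0.05, 0.95, size=n)
    flip_exp = rng.random(n) < 0.5
    flip_out = rng.random(n) < 0.5
    chroms, positions, r2 = _block_layout(cfg)

    def _records(betas, ses, eafs, flips, n_sample):
        recs = []
        for j in range(n):
            if j in pal_idx:
                a1, a2 = _PALINDROMIC_PAIRS[j % len(_PALINDROMIC_PAIRS)]
            else:
                a1, a2 = _NONPALINDROMIC_PAIRS[j % len(_NONPALINDROMIC_PAIRS)]
            beta, se, freq = float(betas[j]), float(ses[j]), float(eafs[j])
            ea, oa = a1, a2
            if flips[j]:
                ea, oa, beta, freq = oa, ea, -beta, 1.0 - freq
            recs.append(
                AssociationRecord(
                    snp_id=f"rs{j + 1:06d}",
                    chrom=chroms[j],
                    pos=positions[j],
                    effect_allele=ea,
                    other_allele=oa,
                    beta=beta,
                    se=se,
                    pvalue=pvalue_from_z(beta, se),
                    eaf=freq,
                    n=n_sample,
                )
            )
        return recs

    exposure = SumstatsTable(
        records=tuple(_records(bx, se_x_out, eaf, flip_exp, 500_000)),
        trait_label="sim_exposure",
        trait_type="quantitative",
    )
    outcome = SumstatsTable(
        records=tuple(_records(by, se_y_out, eaf, flip_out, 900_000)),
        trait_label="sim_outcome",
        trait_type="binary",
    )
    ld = LDMatrix(
        snp_ids=exposure.snp_ids, chrom=tuple(chroms), pos=tuple(positions), r2=r2
    )
    truth = SimTruth(
        beta_causal=cfg.beta_causal,
        gamma=tuple(float(g) for g in gamma),
        alpha=tuple(float(a) for a in alpha),
        seed=cfg.seed,
    )
    return exposure, outcome, ld, truth


def _child_seeds(seed: int, n: int) -> list[int]:
    # independent, reproducible per-replicate streams below 2^31
    ss = np.random.SeedSequence(seed)
    return [int(s) for s in ss.generate_state(n) % (2**31 - 1)]


def calibration_study(
    cfg: SimConfig,
    n_reps: int = 200,
    alpha: float = 0.05,
    methods: Sequence[str] = ("ivw_fe", "ivw_re", "weighted_median", "egger"),
    selection: SelectionConfig | None = None,
    harmonize_cfg: HarmonizeConfig | None = None,
    n_boot: int = 200,
    outcome_screen: bool = False,
) -> pd.DataFrame:
    """Monte-Carlo calibration of the estimator suite under known truth.

    Each replicate simulates a pair from ``cfg`` (with an independent
    sub-seed), runs the full pipeline (selection, clumping, strength
    screen, outcome-overlap exclusion, harmonization) and applies the
    requested estimators. Returns a tidy table with one row per
    method: rejection rate at ``alpha``, mean estimate, empirical SD of
    the estimates, mean model SE, and 95% CI coverage of the truth.
    An ``egger_intercept`` row (added whenever ``egger`` is requested)
    is judged against the mean directional pleiotropy rather than the
    causal effect.

    The selection significance threshold defaults to genome-wide (5e-8)
    rather than the blood-trait 5e-9 so that moderately powered
    simulated instruments survive. The outcome-overlap screen defaults
    to *off* here (``outcome_screen=False``): under a real causal
    effect or simulated pleiotropy that screen removes precisely the
    instruments whose estimator behaviour is being calibrated, masking
    the biases the study is meant to expose.
    """
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    from mrpipe import pipeline  # deferred: pipeline imports this module

    selection = selection or SelectionConfig(p_threshold=5e-8)
    harmonize_cfg = harmonize_cfg or HarmonizeConfig()
    true_intercept = (
        cfg.pleiotropy_mean if cfg.pleiotropy_mode == "directional" else 0.0
    )
    targets = {m: cfg.beta_causal for m in methods}
    if "egger" in methods:
        targets["egger_intercept"] = true_intercept

    rows: dict[str, dict[str, list[float]]] = {
        m: {"beta": [], "se": [], "reject": [], "cover": []} for m in targets
    }
    seeds = _child_seeds(cfg.seed, n_reps)
    n_used = 0
    for rep_seed in seeds:
        rep_cfg = replace(cfg, seed=rep_seed)
        exposure, outcome, ld, truth = simulate_pair(rep_cfg)
        instruments = pipeline.select_instruments(
            exposure, outcome, ld, selection, outcome_screen=outcome_screen
        )
        harmonized, _ = harmonize(instruments, outcome, harmonize_cfg)
        if len(harmonized) < 3:
            logger.debug("replicate %d: only %d instruments, skipped", rep_seed, len(harmonized))
            continue
        n_used += 1
        results: dict[str, tuple[float, float, float, float]] = {}
        if "ivw_fe" in methods:
            est, _ = ivw(harmonized, "fixed")
            results["ivw_fe"] = (est.beta, est.se, est.pvalue, _covers(est, cfg.beta_causal))
        if "ivw_re" in methods:
            est, _ = ivw(harmonized, "random")
            results["ivw_re"] = (est.beta, est.se, est.pvalue, _covers(est, cfg.beta_causal))
        if "weighted_median" in methods:
            est = weighted_median(harmonized, n_boot=n_boot, seed=rep_seed)
            results["weighted_median"] = (
                est.beta, est.se, est.pvalue, _covers(est, cfg.beta_causal)
            )
        if "egger" in methods:
            egg = egger(harmonized)
            results["egger"] = (
                egg.slope.beta, egg.slope.se, egg.slope.pvalue,
                _covers(egg.slope, cfg.beta_causal),
            )
            ci_low = egg.intercept - 1.959963984540054 * egg.intercept_se
            ci_high = egg.intercept + 1.959963984540054 * egg.intercept_se
            results["egger_intercept"] = (
                egg.intercept, egg.intercept_se, egg.intercept_pvalue,
                float(ci_low <= true_intercept <= ci_high),
            )
        for m, (beta, se, p, cover) in results.items():
            rows[m]["beta"].append(beta)
            rows[m]["se"].append(se)
            rows[m]["reject"].append(float(p < alpha))
            rows[m]["cover"].append(cover)

    out = []
    for m, acc in rows.items():
        if not acc["beta"]:
            continue
        beta = np.asarray(acc["beta"])
        out.append(
            {
                "method": m,
                "truth": targets[m],
                "n_reps": len(beta),
                "reject_rate": float(np.mean(acc["reject"])),
                "mean_estimate": float(beta.mean()),
                "empirical_se": float(beta.std(ddof=1)) if len(beta) > 1 else float("nan"),
                "mean_model_se": float(np.mean(acc["se"])),
                "coverage": float(np.mean(acc["cover"])),
            }
        )
    logger.info("calibration: %d of %d replicates usable", n_used, n_reps)
    return pd.DataFrame(out)


def _covers(est, truth: float) -> float:
    return float(est.ci_low <= truth <= est.ci_high)
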