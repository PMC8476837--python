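"""Synthetic two-sample GWAS summary statistics with known ground truth.

The generator emulates the structure of a metabolome-exposure / disease-
outcome screen on the summary-statistic scale: per-SNP exposure effects
gamma_j observed with sampling noise at study-scale n1, outcome effects
Gamma_j = beta * gamma_j + alpha_j (+ noise at n2) on the log-odds scale,
optional LD blocks, and multiple exposures that may share instruments.
Default sample sizes mirror a 7,824-person metabolomics study and a
~977,000-person case-control outcome meta-analysis.

Approximate standard errors follow the allele-frequency formula
``sigma ~= 1 / sqrt(2 n p (1 - p))``; outcome effects are generated directly
on the summary (log-odds) scale rather than via individual-level
case-control sampling, which keeps desk-scale runtimes.

All randomness flows from a single seed through per-component
``SeedSequence`` splits, so adding exposures does not perturb existing ones.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

from .exceptions import ConfigurationError
from .io import EXPOSURE, OUTCOME, HarmonizedSet, LDPanel, SummaryTable

from scipy import stats

PLEIOTROPY_REGIMES = ("none", "balanced", "directional", "inside_violating")

# non-palindromic allele pairs only; palindromic SNPs are planted explicitly
_ALLELE_PAIRS = [("A", "G"), ("A", "C"), ("T", "G"), ("T", "C"),
                 ("G", "A"), ("C", "A"), ("G", "T"), ("C", "T")]

#: slope of alpha on gamma in the InSIDE-violating regime
_INSIDE_SLOPE = 0.5


@dataclass
class SimConfig:
    """Full parameterization of the two-sample summary-statistic generator.

    ``gamma_dist = (mean, sd)`` governs true SNP-exposure effects (per-SD
    units); ``true_beta`` is the causal log-odds-per-SD effect carried by the
    exposures in ``causal_exposures``; ``pleiotropy`` selects the direct-
    effect regime applied to an ``invalid_fraction`` share of SNPs;
    ``ld_blocks`` is a list of ``(block_size, dosage_correlation)``;
    ``n_causal`` limits how many SNPs each exposure truly affects (``None``
    means all); ``shared_snp_rate`` is the probability that a causal SNP of
    exposure e is also planted in exposure e+1.
    """

    n_snp: int = 50
    n_exposure_sample: int = 7_824
    n_outcome_sample: int = 977_323
    maf_range: tuple[float, float] = (0.05, 0.45)
    true_beta: float = 0.2
    gamma_dist: tuple[float, float] = (0.10, 0.03)
    pleiotropy: str = "none"
    mean_alpha: float = 0.0
    sd_alpha: float = 0.05
    invalid_fraction: float = 0.3
    ld_blocks: list[tuple[int, float]] = field(default_factory=list)
    n_exposures: int = 1
    n_causal: int | None = None
    causal_exposures: tuple[int, ...] = (0,)
    shared_snp_rate: float = 0.0
    seed: int = 0

    def validate(self) -> None:
        lo, hi = self.maf_range
        if not (0 < lo <= hi < 0.5):
            raise ConfigurationError(f"maf_range must satisfy 0 < lo <= hi < 0.5, got {self.maf_range}")
        if not (0 <= self.invalid_fraction <= 1):
            raise ConfigurationError("invalid_fraction must be in [0,1]")
        if self.n_exposure_sample <= 0 or self.n_outcome_sample <= 0:
            raise ConfigurationError("sample sizes must be positive")
        if self.pleiotropy not in PLEIOTROPY_REGIMES:
            raise ConfigurationError(f"unknown pleiotropy regime {self.pleiotropy!r}")
        if sum(b for b, _ in self.ld_blocks) > self.n_snp:
            raise ConfigurationError("ld_blocks exceed n_snp")


@dataclass
class TruthRecord:
    """Every latent quantity behind one simulated study."""

    true_beta: float
    maf: np.ndarray
    gamma_true: dict[str, np.ndarray]   # exposure_id -> per-SNP true effects
    alpha: np.ndarray
    Gamma_true: np.ndarray
    causal: dict[str, np.ndarray]       # exposure_id -> causal SNP indices
    invalid: np.ndarray                 # indices carrying pleiotropy


@dataclass
class SimStudy:
    exposures: list[SummaryTable]
    outcome: SummaryTable
    panel: LDPanel
    truth: TruthRecord

    def harmonized(self, exposure_index: int = 0,
                   snp_indices=None) -> HarmonizedSet:
        """Direct harmonized view (the generator shares allele orientation)."""
        e = self.exposures[exposure_index].df
        o = self.outcome.df
        idx = np.arange(len(e)) if snp_indices is None else np.asarray(snp_indices)
        return HarmonizedSet.from_arrays(
            gamma=e["beta"].to_numpy()[idx], sigma_x=e["se"].to_numpy()[idx],
            Gamma=o["beta"].to_numpy()[idx], sigma_y=o["se"].to_numpy()[idx],
            snp_ids=[e["snp_id"].iloc[i] for i in idx],
            exposure_id=self.exposures[exposure_index].trait_id,
            outcome_id=self.outcome.trait_id)


def _se_summary(n: int, maf: np.ndarray) -> np.ndarray:
    """First-order SE of a per-allele GWAS effect at sample size n."""
    return 1.0 / np.sqrt(2.0 * n * maf * (1.0 - maf))


def _genome(config: SimConfig, rng: np.random.Generator):
    """SNP ids, chrom, pos, mafs, alleles, and the LD panel.

    SNPs not covered by ``ld_blocks`` are placed >10 Mb apart (alternating
    chromosomes) so they never interact under the default clumping window;
    block members sit 10 kb apart with analytic within-block r^2 = r^2.
    """
    J = config.n_snp
    snp_ids = [f"rs{i + 1:06d}" for i in range(J)]
    maf = rng.uniform(*config.maf_range, size=J)
    pair_idx = rng.integers(0, len(_ALLELE_PAIRS), size=J)
    ea = [_ALLELE_PAIRS[i][0] for i in pair_idx]
    oa = [_ALLELE_PAIRS[i][1] for i in pair_idx]

    chrom = np.empty(J, dtype=object)
    pos = np.empty(J, dtype=int)
    block_of = np.full(J, -1)
    i = 0
    for b, (size, _r) in enumerate(config.ld_blocks):
        c = str(b % 22 + 1)
        start = 1_000_000 + b * 50_000_000
        for k in range(size):
            chrom[i], pos[i], block_of[i] = c, start + k * 10_000, b
            i += 1
    j = 0
    while i < J:
        chrom[i] = str(j % 22 + 1)
        pos[i] = 200_000_000 + (j // 22) * 11_000_000
        i += 1
        j += 1

    panel = LDPanel(snp_ids)
    i = 0
    for size, r in config.ld_blocks:
        for a in range(i, i + size):
            for b in range(a + 1, i + size):
                panel.set_r2(snp_ids[a], snp_ids[b], r ** 2)
        i += size
    meta = pd.DataFrame({"snp_id": snp_ids, "chrom": chrom, "pos": pos,
                         "eaf": maf, "effect_allele": ea, "other_allele": oa})
    return meta, maf, panel


def _causal_sets(config: SimConfig, rngs) -> dict[int, np.ndarray]:
    """Disjoint round-robin causal allocations plus planted sharing."""
    J = config.n_snp
    if config.n_causal is None:
        return {e: np.arange(J) for e in range(config.n_exposures)}
    sets = {}
    for e in range(config.n_exposures):
        base = (np.arange(config.n_causal) + e * config.n_causal) % J
        sets[e] = np.unique(base)
    for e in range(1, config.n_exposures):
        share = rngs[e].random(len(sets[e - 1])) < config.shared_snp_rate
        if share.any():
            sets[e] = np.unique(np.concatenate([sets[e], sets[e - 1][share]]))
    return sets


def simulate_two_sample(config: SimConfig) -> SimStudy:
    """Generate exposure table(s), an outcome table, an LD panel, and truth."""
    config.validate()
    J = config.n_snp
    rng_genome = np.random.default_rng(np.random.SeedSequence([config.seed, 0]))
    rng_exp = [np.random.default_rng(np.random.SeedSequence([config.seed, 1, e]))
               for e in range(config.n_exposures)]
    rng_out = np.random.default_rng(np.random.SeedSequence([config.seed, 2]))

    meta, maf, panel = _genome(config, rng_genome)
    sx = _se_summary(config.n_exposure_sample, maf)
    sy = _se_summary(config.n_outcome_sample, maf)
    causal = _causal_sets(config, rng_exp)

    mean_g, sd_g = config.gamma_dist
    exposures, gamma_true_all = [], {}
    for e in range(config.n_exposures):
        gamma_true = np.zeros(J)
        idx = causal[e]
        gamma_true[idx] = rng_exp[e].normal(mean_g, sd_g, size=len(idx))
        gamma_hat = gamma_true + rng_exp[e].normal(0.0, sx)
        pval = 2.0 * stats.norm.sf(np.abs(gamma_hat / sx))
        eid = f"E{e + 1:02d}"
        df = meta.copy()
        df["beta"], df["se"], df["pval"] = gamma_hat, sx, pval
        df["n"] = config.n_exposure_sample
        exposures.append(SummaryTable(eid, EXPOSURE, df))
        gamma_true_all[eid] = gamma_true

    # direct (pleiotropic) outcome effects
    alpha = np.zeros(J)
    n_invalid = int(round(config.invalid_fraction * J))
    invalid = rng_out.choice(J, size=n_invalid, replace=False) \
        if n_invalid else np.array([], dtype=int)
    if config.pleiotropy != "none" and n_invalid:
        g0 = gamma_true_all["E01"]
        if config.pleiotropy == "balanced":
            alpha[invalid] = rng_out.normal(0.0, config.sd_alpha, n_invalid)
        elif config.pleiotropy == "directional":
            alpha[invalid] = rng_out.normal(config.mean_alpha, config.sd_alpha,
                                            n_invalid)
        else:  # inside_violating: direct effects track instrument strength
            alpha[invalid] = (config.mean_alpha
                              + _INSIDE_SLOPE * (g0[invalid] - g0[invalid].mean())
                              + rng_out.normal(0.0, config.sd_alpha, n_invalid))

    Gamma_true = alpha.copy()
    for e in config.causal_exposures:
        if e < config.n_exposures:
            Gamma_true = Gamma_true + config.true_beta * gamma_true_all[f"E{e + 1:02d}"]
    Gamma_hat = Gamma_true + rng_out.normal(0.0, sy)
    odf = meta.copy()
    odf["beta"], odf["se"] = Gamma_hat, sy
    odf["pval"] = 2.0 * stats.norm.sf(np.abs(Gamma_hat / sy))
    odf["n"] = config.n_outcome_sample
    outcome = SummaryTable("outcome", OUTCOME, odf)

    truth = TruthRecord(config.true_beta, maf, gamma_true_all, alpha,
                        Gamma_true,
                        {f"E{e + 1:02d}": causal[e] for e in causal}, invalid)
    return SimStudy(exposures, outcome, panel, truth)


def simulate_dosages(n_samples: int, mafs, blocks, rng) -> pd.DataFrame:
    """Allele-dosage matrix (SNPs x samples) with exchangeable block LD.

    ``blocks`` lists ``(size, r)``; SNPs beyond the blocks are independent.
    Within a block each haplotype tracks the lead so that the dosage
    correlation is approximately r (the conditional allele probability is
    shifted by ``r * (sd_member / sd_lead) * (lead - maf_lead)``, which gives
    correlation r exactly when no clipping occurs).
    """
    mafs = np.asarray(mafs, dtype=float)
    J = len(mafs)
    dosage = np.empty((J, n_samples))
    i = 0
    for size, r in blocks:
        lead_h = rng.random((2, n_samples)) < mafs[i]
        dosage[i] = lead_h.sum(axis=0)
        sd_lead = np.sqrt(mafs[i] * (1 - mafs[i]))
        for k in range(1, size):
            sd_k = np.sqrt(mafs[i + k] * (1 - mafs[i + k]))
            p_cond = mafs[i + k] + r * (sd_k / sd_lead) * (lead_h - mafs[i])
            h = rng.random((2, n_samples)) < np.clip(p_cond, 0, 1)
            dosage[i + k] = h.sum(axis=0)
        i += size
    for k in range(i, J):
        dosage[k] = rng.binomial(2, mafs[k], size=n_samples)
    index = [f"rs{i + 1:06d}" for i in range(J)]
    cols = [f"s{i + 1}" for i in range(n_samples)]
    return pd.DataFrame(dosage, index=index, columns=cols)


# ---------------------------------------------------------------------------
# on-disk fixture study
# ---------------------------------------------------------------------------

@dataclass
class FixtureStudy:
    """Paths and planted ground truth of a ready-to-run batch study."""

    out_dir: str
    exposure_paths: list[str]
    outcome_path: str
    panel_path: str
    exclusion_path: str
    truth_path: str
    config_path: str
    n_snp: int
    n_exposures: int
    true_beta: float
    causal_exposure_id: str
    two_iv_exposure_id: str
    shared_snp: str
    shared_exposure_ids: tuple[str, str]
    excluded_snp: str
    excluded_exposure_id: str
    palindromic_snp: str
    outlier_snp: str
    ld_pair: tuple[str, str]
    ld_pair_exposure_id: str


def make_fixture_study(scale: str = "small", seed: int = 0,
                       out_dir: str | os.PathLike = "fixture_study"
                       ) -> FixtureStudy:
    """Write a complete batch study exercising every pipeline stage.

    The study plants, at known locations: one causal exposure (E01, all
    others null on the outcome), one MR-PRESSO outlier among E01's
    instruments, one exposure with only two instruments (E02), one SNP
    instrumenting two exposures (E03/E04), one exclusion-listed instrument
    (E05), one palindromic instrument written allele-swapped in the outcome
    file (E06), and one within-window LD pair (E07).
    """
    if scale == "small":
        n_exp, J, per_exp = 20, 500, 12
    elif scale == "medium":
        n_exp, J, per_exp = 40, 2000, 15
    else:
        raise ConfigurationError(f"unknown fixture scale {scale!r}")
    n1, n2 = 7_824, 100_000
    true_beta = 0.2

    rng_genome = np.random.default_rng(np.random.SeedSequence([seed, 0]))
    rng_exp = [np.random.default_rng(np.random.SeedSequence([seed, 1, e]))
               for e in range(n_exp)]
    rng_out = np.random.default_rng(np.random.SeedSequence([seed, 2]))

    snp_ids = [f"rs{i + 1:06d}" for i in range(J)]
    maf = rng_genome.uniform(0.10, 0.40, size=J)
    pair_idx = rng_genome.integers(0, len(_ALLELE_PAIRS), size=J)
    ea = np.array([_ALLELE_PAIRS[i][0] for i in pair_idx], dtype=object)
    oa = np.array([_ALLELE_PAIRS[i][1] for i in pair_idx], dtype=object)
    chrom = np.array([str(i % 22 + 1) for i in range(J)], dtype=object)
    pos = np.array([1_000_000 + (i // 22) * 11_000_000 for i in range(J)])

    chunks = {e: np.arange(per_exp * e, per_exp * (e + 1)) for e in range(n_exp)}
    chunks[1] = chunks[1][:2]                        # E02: two-IV exposure
    shared_idx = int(chunks[2][0])                   # shared by E03 and E04
    excluded_idx = int(chunks[4][0])                 # on the exclusion list
    palindromic_idx = int(chunks[5][0])              # A/T, swapped in outcome
    ld_lead_idx = int(chunks[6][0])
    ld_partner_idx = J - 1                           # re-sited next to the lead
    outlier_idx = int(chunks[0][0])

    ea[palindromic_idx], oa[palindromic_idx] = "A", "T"
    maf[palindromic_idx] = 0.10
    maf[outlier_idx] = 0.25  # keeps the planted outlier's instrument strong
    chrom[ld_partner_idx] = chrom[ld_lead_idx]
    pos[ld_partner_idx] = pos[ld_lead_idx] + 50_000

    sx = _se_summary(n1, maf)
    sy = _se_summary(n2, maf)

    gamma_true = {}
    for e in range(n_exp):
        g = np.zeros(J)
        g[chunks[e]] = rng_exp[e].normal(0.15, 0.03, size=len(chunks[e]))
        gamma_true[e] = g
    gamma_true[0][outlier_idx] = 0.20                # outlier IV always selected
    gamma_true[1][chunks[1]] = 0.25                  # both E02 IVs clear P<1e-5
    gamma_true[2][shared_idx] = 0.25
    gamma_true[3][shared_idx] = 0.25                 # plants the shared IV
    gamma_true[4][excluded_idx] = 0.25
    gamma_true[5][palindromic_idx] = 0.25
    gamma_true[6][ld_lead_idx] = 0.20
    gamma_true[6][ld_partner_idx] = 0.18             # correlated signal in LD

    exposure_tables = []
    for e in range(n_exp):
        gamma_hat = gamma_true[e] + rng_exp[e].normal(0.0, sx)
        pval = 2.0 * stats.norm.sf(np.abs(gamma_hat / sx))
        exposure_tables.append(pd.DataFrame({
            "SNP": snp_ids, "CHR": chrom, "POS": pos, "EA": ea, "OA": oa,
            "EAF": np.round(maf, 4), "BETA": gamma_hat, "SE": sx,
            "P": pval, "N": n1}))

    Gamma_true = true_beta * gamma_true[0]
    Gamma_hat = Gamma_true + rng_out.normal(0.0, sy)
    Gamma_hat[outlier_idx] += 10.0 * sy[outlier_idx]  # planted PRESSO outlier

    out_ea, out_oa = ea.copy(), oa.copy()
    out_beta, out_eaf = Gamma_hat.copy(), maf.copy()
    # a handful of rows (incl. the palindromic SNP) written allele-swapped to
    # exercise harmonization end to end
    swap = sorted({palindromic_idx, 5, 30, 100} & set(range(J)))
    for i in swap:
        out_ea[i], out_oa[i] = oa[i], ea[i]
        out_beta[i] = -out_beta[i]
        out_eaf[i] = 1.0 - out_eaf[i]
    outcome_table = pd.DataFrame({
        "SNP": snp_ids, "CHR": chrom, "POS": pos, "EA": out_ea, "OA": out_oa,
        "EAF": np.round(out_eaf, 4), "BETA": out_beta, "SE": sy,
        "P": 2.0 * stats.norm.sf(np.abs(out_beta / sy)), "N": n2})

    out_dir = str(out_dir)
    exp_dir = os.path.join(out_dir, "exposures")
    os.makedirs(exp_dir, exist_ok=True)
    exposure_paths = []
    for e, table in enumerate(exposure_tables):
        p = os.path.join(exp_dir, f"E{e + 1:02d}.tsv")
        table.to_csv(p, sep="\t", index=False)
        exposure_paths.append(p)
    outcome_path = os.path.join(out_dir, "outcome.tsv")
    outcome_table.to_csv(outcome_path, sep="\t", index=False)

    panel_path = os.path.join(out_dir, "ld_panel.tsv")
    pd.DataFrame({"SNP_A": [snp_ids[ld_lead_idx]],
                  "SNP_B": [snp_ids[ld_partner_idx]],
                  "R2": [0.8]}).to_csv(panel_path, sep="\t", index=False)

    exclusion_path = os.path.join(out_dir, "exclusion.txt")
    with open(exclusion_path, "w") as fh:
        fh.write("# disease/confounder-associated SNPs\n")
        fh.write(snp_ids[excluded_idx] + "\n")
        fh.write(snp_ids[min(400, J - 2)] + "\n")

    truth_path = os.path.join(out_dir, "truth.tsv")
    rows = []
    for e in range(n_exp):
        for i in np.flatnonzero(gamma_true[e]):
            rows.append({"exposure_id": f"E{e + 1:02d}", "snp_id": snp_ids[i],
                         "gamma_true": gamma_true[e][i],
                         "Gamma_true": Gamma_true[i]})
    pd.DataFrame(rows).to_csv(truth_path, sep="\t", index=False)

    config_path = os.path.join(out_dir, "config.yaml")
    with open(config_path, "w") as fh:
        yaml.safe_dump({"exposures_dir": "exposures", "outcome": "outcome.tsv",
                        "ld_panel": "ld_panel.tsv", "exclusion": "exclusion.txt",
                        "seed": int(seed)}, fh)

    return FixtureStudy(
        out_dir=out_dir, exposure_paths=exposure_paths,
        outcome_path=outcome_path, panel_path=panel_path,
        exclusion_path=exclusion_path, truth_path=truth_path,
        config_path=config_path, n_snp=J, n_exposures=n_exp,
        true_beta=true_beta, causal_exposure_id="E01",
        two_iv_exposure_id="E02", shared_snp=snp_ids[shared_idx],
        shared_exposure_ids=("E03", "E04"), excluded_snp=snp_ids[excluded_idx],
        excluded_exposure_id="E05", palindromic_snp=snp_ids[palindromic_idx],
        outlier_snp=snp_ids[outlier_idx],
        ld_pair=(snp_ids[ld_lead_idx], snp_ids[ld_partner_idx]),
        ld_pair_exposure_id="E07")
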