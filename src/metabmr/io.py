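"""GWAS summary-statistic and LD-reference I/O, plus allele harmonization.

Summary statistics arrive as tab- or comma-separated text with a header row.
The canonical column names are ``SNP, CHR, POS, EA, OA, EAF, BETA, SE, P, N``;
other dialects are accommodated through a ``column_map`` of
``{canonical name: file column name}``.

Harmonization aligns an exposure table and an outcome table onto a common
effect-allele orientation so that every downstream estimator sees the
SNP-exposure effect (gamma) and the SNP-outcome effect (Gamma) measured for
the same allele.  Palindromic (A/T or G/C) variants, whose strand cannot be
resolved from allele labels, are resolved by allele-frequency comparison or
dropped, depending on policy.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .exceptions import AnalysisError, ConfigurationError, InputError

log = logging.getLogger(__name__)

#: canonical file column -> internal field name
CANONICAL_COLUMNS = {
    "SNP": "snp_id",
    "CHR": "chrom",
    "POS": "pos",
    "EA": "effect_allele",
    "OA": "other_allele",
    "EAF": "eaf",
    "BETA": "beta",
    "SE": "se",
    "P": "pval",
    "N": "n",
}
#: internal fields that must be resolvable in every input file
REQUIRED_FIELDS = ("snp_id", "chrom", "pos", "effect_allele", "other_allele",
                   "beta", "se", "pval")
OPTIONAL_FIELDS = ("eaf", "n")

VALID_ALLELES = frozenset("ACGT")
COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}

EXPOSURE = "exposure"
OUTCOME = "outcome"


def is_palindromic(effect_allele: str, other_allele: str) -> bool:
    """True for A/T and G/C pairs, whose strand is ambiguous."""
    return COMPLEMENT.get(effect_allele) == other_allele


# ---------------------------------------------------------------------------
# summary statistics
# ---------------------------------------------------------------------------

@dataclass
class SummaryTable:
    """Per-trait GWAS summary statistics keyed by SNP identifier.

    ``df`` holds one row per SNP with columns ``snp_id, chrom, pos,
    effect_allele, other_allele, eaf, beta, se, pval, n``.  ``snp_id`` is
    unique within a table.
    """

    trait_id: str
    trait_role: str
    df: pd.DataFrame

    def __post_init__(self) -> None:
        if self.trait_role not in (EXPOSURE, OUTCOME):
            raise ConfigurationError(
                f"trait_role must be '{EXPOSURE}' or '{OUTCOME}', got {self.trait_role!r}")
        missing = [c for c in REQUIRED_FIELDS if c not in self.df.columns]
        if missing:
            raise ConfigurationError(f"summary table missing columns: {missing}")
        if len(self.df) == 0:
            raise InputError(f"summary table for {self.trait_id!r} is empty")
        dup = self.df["snp_id"][self.df["snp_id"].duplicated()]
        if len(dup):
            raise InputError(
                f"duplicated snp_id in {self.trait_id!r}: {dup.iloc[0]!r}")
        self.df = self.df.reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.df)

    @property
    def snp_ids(self) -> list[str]:
        return list(self.df["snp_id"])

    def subset(self, snp_ids: Sequence[str]) -> "SummaryTable":
        """Restrict to the given SNPs, preserving this table's row order."""
        keep = self.df[self.df["snp_id"].isin(set(snp_ids))]
        return SummaryTable(self.trait_id, self.trait_role, keep.copy())


def read_summary_stats(path,
                       column_map: Mapping[str, str] | None = None,
                       trait_id: str | None = None,
                       trait_role: str = EXPOSURE) -> SummaryTable:
    """Read a GWAS summary-statistics file into a :class:`SummaryTable`.

    Rows with unparseable ``beta``/``se``/``pval`` (or ``se <= 0``, ``pval``
    outside ``(0, 1]``) are dropped and counted in the log, as are indels and
    multi-allelic records; alleles are upper-cased.  A duplicated ``snp_id``
    or an empty result raises :class:`InputError`; a missing required column
    raises :class:`ConfigurationError` naming the column.
    """
    column_map = dict(column_map or {})
    raw = pd.read_csv(path, sep=None, engine="python", dtype=str)
    raw.columns = [str(c).strip() for c in raw.columns]

    rename: dict[str, str] = {}
    for canonical, internal in CANONICAL_COLUMNS.items():
        file_col = column_map.get(canonical, canonical)
        if file_col in raw.columns:
            rename[file_col] = internal
        elif internal in REQUIRED_FIELDS:
            raise ConfigurationError(
                f"missing required column {file_col!r} (field {canonical}) in {path}")
    df = raw.rename(columns=rename)
    for internal in OPTIONAL_FIELDS:
        if internal not in df.columns:
            df[internal] = np.nan
    df = df[list(CANONICAL_COLUMNS.values())].copy()

    df["snp_id"] = df["snp_id"].astype(str).str.strip()
    df["chrom"] = df["chrom"].astype(str).str.strip()
    for col in ("pos", "eaf", "beta", "se", "pval", "n"):
        df[col] = pd.to_numeric(df[col], errors="coerce")
    for col in ("effect_allele", "other_allele"):
        df[col] = df[col].astype(str).str.strip().str.upper()

    n0 = len(df)
    parse_bad = (df["beta"].isna() | df["se"].isna() | df["pval"].isna()
                 | df["pos"].isna() | (df["se"] <= 0)
                 | (df["pval"] <= 0) | (df["pval"] > 1))
    allele_bad = (~df["effect_allele"].isin(VALID_ALLELES)
                  | ~df["other_allele"].isin(VALID_ALLELES)
                  | (df["effect_allele"] == df["other_allele"]))
    df = df[~(parse_bad | allele_bad)].copy()
    n_parse, n_allele = int(parse_bad.sum()), int((allele_bad & ~parse_bad).sum())
    if n_parse or n_allele:
        log.info("%s: dropped %d unparseable and %d non-biallelic-SNP rows "
                 "of %d", path, n_parse, n_allele, n0)
    if len(df) == 0:
        raise InputError(f"no usable rows in {path}")

    oob = (df["eaf"] < 0) | (df["eaf"] > 1)
    if oob.any():
        log.info("%s: %d eaf values outside [0,1] set to missing", path, int(oob.sum()))
        df.loc[oob, "eaf"] = np.nan
    df["pos"] = df["pos"].astype(int)

    tid = trait_id if trait_id is not None else _stem(path)
    return SummaryTable(tid, trait_role, df.reset_index(drop=True))


def _stem(path) -> str:
    import os
    return os.path.splitext(os.path.basename(str(path)))[0]


# ---------------------------------------------------------------------------
# LD reference
# ---------------------------------------------------------------------------

class LDPanel:
    """Pairwise squared-correlation (r^2) reference for a set of SNPs.

    Absent pairs default to ``r2 = 0`` and ``r2(i, i) = 1``.  Panels can be
    built from a pairwise ``SNP_A / SNP_B / R2`` table or from a plain-text
    allele-dosage matrix (SNPs x samples), in which case r^2 is the squared
    sample correlation of dosages.
    """

    def __init__(self, snp_ids: Sequence[str],
                 positions: pd.DataFrame | None = None) -> None:
        self.snp_ids = list(dict.fromkeys(snp_ids))
        self._snps = set(self.snp_ids)
        self._r2: dict[tuple[str, str], float] = {}
        self.positions = positions

    def __contains__(self, snp_id: str) -> bool:
        return snp_id in self._snps

    def __len__(self) -> int:
        return len(self.snp_ids)

    @staticmethod
    def _key(a: str, b: str) -> tuple[str, str]:
        return (a, b) if a <= b else (b, a)

    def set_r2(self, a: str, b: str, value: float) -> None:
        if not (-1e-9 <= value <= 1 + 1e-9):
            raise InputError(f"r2({a},{b})={value} outside [0,1]")
        if a == b:
            return
        for s in (a, b):
            if s not in self._snps:
                self._snps.add(s)
                self.snp_ids.append(s)
        self._r2[self._key(a, b)] = float(min(max(value, 0.0), 1.0))

    def r2(self, a: str, b: str) -> float:
        if a == b:
            return 1.0
        return self._r2.get(self._key(a, b), 0.0)

    @classmethod
    def from_pairwise(cls, pairs: pd.DataFrame) -> "LDPanel":
        panel = cls([])
        for a, b, v in pairs[["SNP_A", "SNP_B", "R2"]].itertuples(index=False):
            panel.set_r2(str(a), str(b), float(v))
        return panel

    @classmethod
    def from_genotypes(cls, dosages: pd.DataFrame,
                       positions: pd.DataFrame | None = None,
                       min_r2: float = 1e-12) -> "LDPanel":
        """Build a panel from a SNP-by-sample dosage matrix (index = snp_id)."""
        snps = [str(s) for s in dosages.index]
        panel = cls(snps, positions=positions)
        mat = dosages.to_numpy(dtype=float)
        with np.errstate(invalid="ignore", divide="ignore"):
            corr = np.corrcoef(mat)
        corr = np.atleast_2d(np.nan_to_num(corr, nan=0.0))
        r2 = np.clip(corr ** 2, 0.0, 1.0)
        for i in range(len(snps)):
            for j in range(i + 1, len(snps)):
                if r2[i, j] > min_r2:
                    panel.set_r2(snps[i], snps[j], float(r2[i, j]))
        return panel


def read_ld_panel(path, format: str = "pairwise") -> LDPanel:
    """Read an LD reference, either a pairwise r^2 table or a dosage matrix.

    ``pairwise`` files carry columns ``SNP_A, SNP_B, R2``; ``genotype`` files
    carry a ``SNP`` column (optionally ``CHR``/``POS``) followed by one
    numeric dosage column per sample.
    """
    df = pd.read_csv(path, sep=None, engine="python")
    df.columns = [str(c).strip() for c in df.columns]
    if format == "pairwise":
        upper = {c.upper(): c for c in df.columns}
        needed = ["SNP_A", "SNP_B", "R2"]
        missing = [c for c in needed if c not in upper]
        if missing:
            raise ConfigurationError(f"pairwise LD file missing columns {missing}")
        pairs = df.rename(columns={upper[c]: c for c in needed})
        if not np.isfinite(pairs["R2"].to_numpy(dtype=float)).all():
            raise InputError("non-numeric r2 in pairwise LD file")
        return LDPanel.from_pairwise(pairs)
    if format == "genotype":
        upper = {c.upper(): c for c in df.columns}
        if "SNP" not in upper:
            raise ConfigurationError("genotype LD file missing SNP column")
        meta_cols = [upper[c] for c in ("SNP", "CHR", "POS") if c in upper]
        positions = None
        if len(meta_cols) == 3:
            positions = df[meta_cols].rename(
                columns=dict(zip(meta_cols, ["snp_id", "chrom", "pos"])))
        dosages = df.drop(columns=meta_cols).astype(float)
        dosages.index = df[upper["SNP"]].astype(str)
        return LDPanel.from_genotypes(dosages, positions=positions)
    raise ConfigurationError(f"unknown LD panel format {format!r}")


# ---------------------------------------------------------------------------
# harmonization
# ---------------------------------------------------------------------------

@dataclass
class HarmonizedSet:
    """Allele-aligned per-SNP effect arrays for one exposure-outcome pair.

    Columns of ``df``: ``snp_id, gamma, sigma_x, Gamma, sigma_y,
    eaf_exposure, eaf_outcome, palindromic, flipped``.
    """

    exposure_id: str
    outcome_id: str
    df: pd.DataFrame
    drop_log: dict[str, list[str]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if len(self.df):
            if (self.df["sigma_x"] <= 0).any() or (self.df["sigma_y"] <= 0).any():
                raise InputError("harmonized standard errors must be positive")
        self.df = self.df.reset_index(drop=True)

    @property
    def n_snp(self) -> int:
        return len(self.df)

    @property
    def snp_ids(self) -> list[str]:
        return list(self.df["snp_id"])

    @property
    def gamma(self) -> np.ndarray:
        return self.df["gamma"].to_numpy(dtype=float)

    @property
    def sigma_x(self) -> np.ndarray:
        return self.df["sigma_x"].to_numpy(dtype=float)

    @property
    def Gamma(self) -> np.ndarray:
        return self.df["Gamma"].to_numpy(dtype=float)

    @property
    def sigma_y(self) -> np.ndarray:
        return self.df["sigma_y"].to_numpy(dtype=float)

    def subset(self, index) -> "HarmonizedSet":
        """Row subset by boolean mask or positional indices."""
        idx = np.asarray(index)
        sub = self.df[idx] if idx.dtype == bool else self.df.iloc[idx]
        return HarmonizedSet(self.exposure_id, self.outcome_id, sub.copy())

    def drop_snp(self, snp_id: str) -> "HarmonizedSet":
        keep = self.df["snp_id"] != snp_id
        return HarmonizedSet(self.exposure_id, self.outcome_id, self.df[keep].copy())

    @classmethod
    def from_arrays(cls, gamma, sigma_x, Gamma, sigma_y,
                    snp_ids: Sequence[str] | None = None,
                    exposure_id: str = "exposure",
                    outcome_id: str = "outcome") -> "HarmonizedSet":
        gamma = np.asarray(gamma, dtype=float)
        if snp_ids is None:
            snp_ids = [f"snp{i + 1}" for i in range(len(gamma))]
        df = pd.DataFrame({
            "snp_id": list(snp_ids),
            "gamma": gamma,
            "sigma_x": np.asarray(sigma_x, dtype=float),
            "Gamma": np.asarray(Gamma, dtype=float),
            "sigma_y": np.asarray(sigma_y, dtype=float),
            "eaf_exposure": np.nan,
            "eaf_outcome": np.nan,
            "palindromic": False,
            "flipped": False,
        })
        return cls(exposure_id, outcome_id, df)


def harmonize(exposure: SummaryTable,
              outcome: SummaryTable,
              palindromic_policy: str = "infer",
              maf_infer_threshold: float = 0.42) -> HarmonizedSet:
    """Align exposure and outcome tables onto the exposure's effect alleles.

    Rules, applied to the snp_id intersection:

    * matching allele pairs are taken as-is;
    * outcome alleles listed in swapped order get ``Gamma`` negated and
      ``eaf_outcome`` complemented (``flipped=True``);
    * non-palindromic pairs that match after strand complementing are aligned
      the same way;
    * palindromic SNPs: ``policy='drop'`` removes them; ``policy='infer'``
      keeps those with unambiguous frequencies (``min(eaf, 1-eaf) <=
      maf_infer_threshold`` in both studies) and applies a strand correction
      when the two frequencies disagree about which allele is minor; a
      palindromic SNP with missing frequency is dropped;
    * anything else (irreconcilable allele pairs) is dropped and logged.
    """
    if palindromic_policy not in ("infer", "drop"):
        raise ConfigurationError(f"unknown palindromic policy {palindromic_policy!r}")
    merged = exposure.df.merge(outcome.df, on="snp_id", suffixes=("_exp", "_out"))
    if len(merged) == 0:
        raise AnalysisError(
            f"no shared instruments between {exposure.trait_id!r} and "
            f"{outcome.trait_id!r}")

    rows = []
    dropped: dict[str, list[str]] = {"palindromic": [], "non_resolvable": []}
    for rec in merged.itertuples(index=False):
        ea1, oa1 = rec.effect_allele_exp, rec.other_allele_exp
        ea2, oa2 = rec.effect_allele_out, rec.other_allele_out
        Gamma, eaf_out, flipped = rec.beta_out, rec.eaf_out, False
        palindromic = is_palindromic(ea1, oa1)

        if (ea2, oa2) == (ea1, oa1):
            pass
        elif (ea2, oa2) == (oa1, ea1):
            Gamma, eaf_out, flipped = -Gamma, 1.0 - eaf_out, True
        elif not palindromic and (COMPLEMENT.get(ea2), COMPLEMENT.get(oa2)) == (ea1, oa1):
            pass  # strand difference only
        elif not palindromic and (COMPLEMENT.get(ea2), COMPLEMENT.get(oa2)) == (oa1, ea1):
            Gamma, eaf_out, flipped = -Gamma, 1.0 - eaf_out, True
        else:
            dropped["non_resolvable"].append(rec.snp_id)
            continue

        if palindromic:
            if palindromic_policy == "drop":
                dropped["palindromic"].append(rec.snp_id)
                continue
            eaf_exp = rec.eaf_exp
            if not (np.isfinite(eaf_exp) and np.isfinite(eaf_out)):
                dropped["palindromic"].append(rec.snp_id)
                continue
            if (min(eaf_exp, 1 - eaf_exp) > maf_infer_threshold
                    or min(eaf_out, 1 - eaf_out) > maf_infer_threshold):
                dropped["palindromic"].append(rec.snp_id)  # ambiguous near 0.5
                continue
            if (eaf_exp - 0.5) * (eaf_out - 0.5) < 0:
                # frequencies disagree about the minor allele: strand flip
                Gamma, eaf_out, flipped = -Gamma, 1.0 - eaf_out, not flipped

        rows.append({
            "snp_id": rec.snp_id,
            "gamma": rec.beta_exp,
            "sigma_x": rec.se_exp,
            "Gamma": Gamma,
            "sigma_y": rec.se_out,
            "eaf_exposure": rec.eaf_exp,
            "eaf_outcome": eaf_out,
            "palindromic": palindromic,
            "flipped": flipped,
        })

    for reason, snps in dropped.items():
        if snps:
            log.info("harmonize(%s, %s): dropped %d %s SNPs",
                     exposure.trait_id, outcome.trait_id, len(snps), reason)
    if not rows:
        raise AnalysisError(
            f"no shared instruments between {exposure.trait_id!r} and "
            f"{outcome.trait_id!r} after harmonization")
    df = pd.DataFrame(rows)
    return HarmonizedSet(exposure.trait_id, outcome.trait_id, df, drop_log=dropped)
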