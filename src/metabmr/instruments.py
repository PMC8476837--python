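"""Instrument selection: significance filter, LD clumping, cross-exposure
restriction, exclusion list, and the per-exposure IV-count filter.

The filters compose in a fixed order (p-value -> clump -> cross-exposure ->
exclusion list -> IV count) and each removal is recorded so the counts at
every stage are auditable.  Defaults follow common two-sample MR practice for
metabolite screens: selection at P < 1e-5, clumping at r^2 = 0.001 within a
10,000 kb window, removal of SNPs instrumenting two or more exposures, and
retention of exposures with between 3 and 100 instruments.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

from .exceptions import ConfigurationError
from .io import LDPanel, SummaryTable

log = logging.getLogger(__name__)

DEFAULT_P_THRESHOLD = 1e-5
DEFAULT_R2_CUTOFF = 0.001
DEFAULT_WINDOW_KB = 10_000
DEFAULT_MIN_IV = 3
DEFAULT_MAX_IV = 100


@dataclass
class InstrumentSet:
    """Instruments retained for one exposure, with per-SNP provenance.

    ``provenance`` maps each SNP ever considered to the stage that removed it
    (or ``"retained"``).
    """

    exposure_id: str
    snp_ids: list[str]
    provenance: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if len(set(self.snp_ids)) != len(self.snp_ids):
            raise ConfigurationError(
                f"duplicate snp_id in instrument set for {self.exposure_id!r}")
        for s in self.snp_ids:
            self.provenance.setdefault(s, "retained")

    def __len__(self) -> int:
        return len(self.snp_ids)

    def removing(self, snps: Iterable[str], reason: str) -> "InstrumentSet":
        drop = set(snps) & set(self.snp_ids)
        prov = dict(self.provenance)
        for s in drop:
            prov[s] = reason
        kept = [s for s in self.snp_ids if s not in drop]
        return InstrumentSet(self.exposure_id, kept, prov)


@dataclass
class FilterTrace:
    """SNP counts after each selection stage; non-increasing by construction."""

    initial: int
    after_pvalue: int = 0
    after_clump: int = 0
    after_restriction: int = 0
    after_exclusion_list: int = 0
    final: int = 0

    def stages(self) -> list[int]:
        return [self.initial, self.after_pvalue, self.after_clump,
                self.after_restriction, self.after_exclusion_list, self.final]

    @property
    def monotonic(self) -> bool:
        s = self.stages()
        return all(a >= b for a, b in zip(s, s[1:]))


def select_by_pvalue(table: SummaryTable,
                     threshold: float = DEFAULT_P_THRESHOLD) -> InstrumentSet:
    """Retain exactly the SNPs with exposure ``pval`` strictly below threshold."""
    df = table.df
    keep = df[df["pval"] < threshold]
    keep = keep.sort_values(["chrom", "pos", "snp_id"], kind="stable")
    return InstrumentSet(table.trait_id, list(keep["snp_id"]))


def ld_clump(candidates: InstrumentSet,
             exposure: SummaryTable,
             panel: LDPanel | None,
             r2_cutoff: float = DEFAULT_R2_CUTOFF,
             window_kb: float = DEFAULT_WINDOW_KB,
             missing_snp_policy: str = "keep") -> InstrumentSet:
    """Greedy LD clumping of candidate instruments.

    Repeatedly takes the unremoved candidate with the smallest exposure
    p-value as an index SNP and removes every other candidate on the same
    chromosome within ``window_kb`` (inclusive distance) whose r^2 with it
    exceeds ``r2_cutoff``.  Ties on p-value break by (chrom, pos, snp_id)
    ascending, so the output is deterministic and order-independent.

    Candidates absent from the panel are retained and logged (``keep``,
    treated as independent) or removed upfront (``drop``).
    """
    if missing_snp_policy not in ("keep", "drop"):
        raise ConfigurationError(f"unknown missing_snp_policy {missing_snp_policy!r}")
    df = exposure.df.set_index("snp_id")
    snps = list(candidates.snp_ids)
    prov = dict(candidates.provenance)

    if panel is not None:
        absent = [s for s in snps if s not in panel]
        if absent:
            log.info("ld_clump(%s): %d candidate SNPs absent from LD panel (%s)",
                     candidates.exposure_id, len(absent), missing_snp_policy)
            if missing_snp_policy == "drop":
                for s in absent:
                    prov[s] = "removed_missing_from_panel"
                snps = [s for s in snps if s not in set(absent)]

    order = sorted(snps, key=lambda s: (df.at[s, "pval"], df.at[s, "chrom"],
                                        df.at[s, "pos"], s))
    window_bp = window_kb * 1000.0
    removed: set[str] = set()
    kept: list[str] = []
    for idx_snp in order:
        if idx_snp in removed:
            continue
        kept.append(idx_snp)
        if panel is None:
            continue
        c, p = df.at[idx_snp, "chrom"], df.at[idx_snp, "pos"]
        for other in order:
            if other == idx_snp or other in removed:
                continue
            if (df.at[other, "chrom"] == c
                    and abs(df.at[other, "pos"] - p) <= window_bp
                    and panel.r2(idx_snp, other) > r2_cutoff):
                removed.add(other)
                prov[other] = f"removed_clump_with_{idx_snp}"
    kept_sorted = [s for s in candidates.snp_ids if s in set(kept)]
    return InstrumentSet(candidates.exposure_id, kept_sorted, prov)


def restrict_cross_exposure(per_exposure: Mapping[str, InstrumentSet],
                            all_exposures: Sequence[SummaryTable],
                            association_threshold: float = DEFAULT_P_THRESHOLD,
                            min_shared: int = 2) -> dict[str, InstrumentSet]:
    """Remove SNPs significantly associated with ``min_shared`` or more exposures.

    A SNP whose exposure p-value is below ``association_threshold`` in at
    least ``min_shared`` of the supplied exposure tables is removed from
    every instrument set (it likely violates the exclusion-restriction
    assumption through shared metabolic regulation).
    """
    counts: dict[str, int] = {}
    for table in all_exposures:
        sig = table.df.loc[table.df["pval"] < association_threshold, "snp_id"]
        for s in sig:
            counts[s] = counts.get(s, 0) + 1
    shared = {s for s, c in counts.items() if c >= min_shared}
    if shared:
        log.info("cross-exposure restriction removes %d SNPs", len(shared))
    return {eid: iset.removing(shared, "removed_cross_exposure")
            for eid, iset in per_exposure.items()}


def apply_exclusion_list(instruments: InstrumentSet,
                         exclusion: Iterable[str]) -> InstrumentSet:
    """Set-difference against a disease/confounder-associated SNP list."""
    return instruments.removing(set(exclusion), "removed_exclusion_list")


def filter_iv_count(per_exposure: Mapping[str, InstrumentSet],
                    min_iv: int = DEFAULT_MIN_IV,
                    max_iv: int = DEFAULT_MAX_IV) -> dict[str, InstrumentSet]:
    """Drop exposures with fewer than ``min_iv`` or more than ``max_iv`` IVs."""
    if min_iv < 1:
        raise ConfigurationError("min_iv must be >= 1")
    return {eid: iset for eid, iset in per_exposure.items()
            if min_iv <= len(iset) <= max_iv}


def read_exclusion_list(path) -> list[str]:
    """One snp_id per line, blank lines and '#' comments ignored."""
    out = []
    with open(path) as fh:
        for line in fh:
            s = line.strip()
            if s and not s.startswith("#"):
                out.append(s)
    return out


def select_instruments(exposures: Sequence[SummaryTable],
                       panel: LDPanel | None = None,
                       exclusion: Sequence[str] = (),
                       p_threshold: float = DEFAULT_P_THRESHOLD,
                       r2_cutoff: float = DEFAULT_R2_CUTOFF,
                       window_kb: float = DEFAULT_WINDOW_KB,
                       min_iv: int = DEFAULT_MIN_IV,
                       max_iv: int = DEFAULT_MAX_IV,
                       cross_exposure_min: int = 2,
                       missing_snp_policy: str = "keep"
                       ) -> tuple[dict[str, InstrumentSet],
                                  dict[str, FilterTrace],
                                  dict[str, str]]:
    """Compose the four filters plus the IV-count rule across all exposures.

    Returns ``(per_exposure instrument sets, per_exposure traces, removed)``
    where ``removed`` maps exposures dropped by the IV-count filter to a
    reason string.
    """
    per: dict[str, InstrumentSet] = {}
    traces: dict[str, FilterTrace] = {}
    for table in exposures:
        trace = FilterTrace(initial=len(table))
        cand = select_by_pvalue(table, p_threshold)
        trace.after_pvalue = len(cand)
        cand = ld_clump(cand, table, panel, r2_cutoff, window_kb,
                        missing_snp_policy=missing_snp_policy)
        trace.after_clump = len(cand)
        per[table.trait_id] = cand
        traces[table.trait_id] = trace

    per = restrict_cross_exposure(per, exposures, p_threshold,
                                  min_shared=cross_exposure_min)
    for eid, iset in per.items():
        traces[eid].after_restriction = len(iset)

    per = {eid: apply_exclusion_list(iset, exclusion) for eid, iset in per.items()}
    for eid, iset in per.items():
        traces[eid].after_exclusion_list = len(iset)

    kept = filter_iv_count(per, min_iv=min_iv, max_iv=max_iv)
    removed: dict[str, str] = {}
    for eid, iset in per.items():
        if eid in kept:
            traces[eid].final = len(iset)
        else:
            traces[eid].final = 0
            removed[eid] = (f"IV count {len(iset)} outside "
                            f"[{min_iv}, {max_iv}]")
    return kept, traces, removed
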