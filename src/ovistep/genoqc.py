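"""Genotype quality control, parentage verification and duplicate handling.

Sample and SNP filters follow the thresholds used in UK national genomic
evaluations (call rate 89.4%, MAF 0.05, HWE p 0.05); parentage is verified
and discovered with the opposing-homozygotes method, and duplicate samples
are resolved by array-density priority (50K > HD > LDv2 > LDv1).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .pedigree import Pedigree

MISSING = -1
ARRAY_PRIORITY = {"50K": 0, "HD": 1, "LDv2": 2, "LDv1": 3}

#: thresholds from the UK cattle genomic-evaluation QC pipeline
DEFAULT_CALL_RATE = 0.894
DEFAULT_MAF = 0.05
DEFAULT_HWE_ALPHA = 0.05
DEFAULT_OH_THRESHOLD = 0.01


class PanelError(ValueError):
    """Malformed genotype panel or incompatible operands."""


class DuplicateConflictError(RuntimeError):
    """Multiple parentage-passing samples for one animal disagree."""


@dataclass
class GenotypePanel:
    """Animals x SNPs allele-count matrix ({0,1,2}, -1 = missing call).

    ``array_labels`` records which SNP array each sample came from; snp_meta
    (indexed by snp id) carries chromosome, position and the two alleles,
    with ``allele_b`` being the counted allele.
    """

    animal_ids: list[str]
    snp_ids: list[str]
    calls: np.ndarray
    array_labels: list[str]
    snp_meta: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        self.calls = np.asarray(self.calls, dtype=np.int8)
        if self.calls.shape != (len(self.animal_ids), len(self.snp_ids)):
            raise PanelError("calls matrix shape does not match id lists")
        bad = ~np.isin(self.calls, (-1, 0, 1, 2))
        if bad.any():
            raise PanelError("calls must be in {0,1,2} or -1 for missing")
        if len(self.array_labels) != len(self.animal_ids):
            raise PanelError("array label per sample required")
        if self.snp_meta is None:
            self.snp_meta = default_snp_meta(self.snp_ids)

    @property
    def n_samples(self) -> int:
        return len(self.animal_ids)

    @property
    def n_snps(self) -> int:
        return len(self.snp_ids)

    def sample_call_rate(self) -> np.ndarray:
        return (self.calls >= 0).mean(axis=1)

    def snp_call_rate(self) -> np.ndarray:
        return (self.calls >= 0).mean(axis=0)

    def row(self, animal: str) -> np.ndarray:
        return self.calls[self.animal_ids.index(animal)]

    def subset(self, sample_idx=None, snp_idx=None) -> "GenotypePanel":
        si = np.arange(self.n_samples) if sample_idx is None else np.asarray(sample_idx)
        sj = np.arange(self.n_snps) if snp_idx is None else np.asarray(snp_idx)
        return GenotypePanel(
            [self.animal_ids[i] for i in si],
            [self.snp_ids[j] for j in sj],
            self.calls[np.ix_(si, sj)].copy(),
            [self.array_labels[i] for i in si],
            self.snp_meta.iloc[sj].copy(),
        )


def default_snp_meta(snp_ids) -> pd.DataFrame:
    return pd.DataFrame(
        {"chrom": "1", "pos": np.arange(1, len(snp_ids) + 1) * 1000,
         "allele_a": "A", "allele_b": "B"},
        index=pd.Index(snp_ids, name="snp"),
    )


@dataclass
class QCReport:
    """Machine-readable record of QC decisions."""

    samples_removed: list = field(default_factory=list)   # (id, reason)
    snps_removed: list = field(default_factory=list)      # (snp, reason, value)
    parentage_changes: list = field(default_factory=list)  # (animal, slot, old, new, rate)

    def to_frames(self) -> dict[str, pd.DataFrame]:
        return {
            "samples_removed": pd.DataFrame(self.samples_removed, columns=["id", "reason"]),
            "snps_removed": pd.DataFrame(self.snps_removed, columns=["snp", "reason", "value"]),
            "parentage_changes": pd.DataFrame(
                self.parentage_changes,
                columns=["animal", "slot", "old", "new", "rate"],
            ),
        }


# ---------------------------------------------------------------------------
# filters
# ---------------------------------------------------------------------------

def filter_samples_by_call_rate(
    panel: GenotypePanel, threshold: float = DEFAULT_CALL_RATE
) -> tuple[GenotypePanel, QCReport]:
    """Drop samples whose non-missing fraction falls below ``threshold``."""
    if not 0 < threshold <= 1:
        raise ValueError("call-rate threshold must be in (0, 1]")
    report = QCReport()
    if panel.n_samples == 0:
        warnings.warn("empty panel passed to sample call-rate filter")
        return panel, report
    cr = panel.sample_call_rate()
    keep = cr >= threshold
    for i in np.flatnonzero(~keep):
        report.samples_removed.append((panel.animal_ids[i], f"call_rate<{threshold}"))
    return panel.subset(sample_idx=np.flatnonzero(keep)), report


def hwe_chi2_pvalues(calls: np.ndarray) -> np.ndarray:
    """One-df chi-square goodness-of-fit p-values against p^2, 2pq, q^2."""
    nonmiss = calls >= 0
    n0 = ((calls == 0) & nonmiss).sum(axis=0).astype(float)
    n1 = (calls == 1).sum(axis=0).astype(float)
    n2 = (calls == 2).sum(axis=0).astype(float)
    n = n0 + n1 + n2
    pvals = np.ones(calls.shape[1])
    with np.errstate(divide="ignore", invalid="ignore"):
        p = (2 * n2 + n1) / (2 * n)
        q = 1 - p
        e0, e1, e2 = n * q**2, 2 * n * p * q, n * p**2
        ok = (n > 0) & (p > 0) & (p < 1)
        chi2 = np.zeros(calls.shape[1])
        chi2[ok] = (
            (n0[ok] - e0[ok]) ** 2 / e0[ok]
            + (n1[ok] - e1[ok]) ** 2 / e1[ok]
            + (n2[ok] - e2[ok]) ** 2 / e2[ok]
        )
        pvals[ok] = stats.chi2.sf(chi2[ok], df=1)
    return pvals


def filter_snps(
    panel: GenotypePanel,
    call_rate: float = DEFAULT_CALL_RATE,
    maf_min: float = DEFAULT_MAF,
    hwe_alpha: float = DEFAULT_HWE_ALPHA,
) -> tuple[GenotypePanel, QCReport]:
    """SNP-level QC: call rate, minor allele frequency, HWE chi-square."""
    if panel.n_snps == 0:
        return panel, QCReport()
    report = QCReport()
    cr = panel.snp_call_rate()
    nonmiss = panel.calls >= 0
    with np.errstate(invalid="ignore"):
        p = np.where(
            nonmiss.sum(axis=0) > 0,
            np.where(nonmiss, panel.calls, 0).sum(axis=0) / (2 * np.maximum(nonmiss.sum(axis=0), 1)),
            np.nan,
        )
    maf = np.minimum(p, 1 - p)
    pv = hwe_chi2_pvalues(panel.calls)
    keep = np.ones(panel.n_snps, dtype=bool)
    for j in range(panel.n_snps):
        if cr[j] < call_rate:
            report.snps_removed.append((panel.snp_ids[j], "call_rate", float(cr[j])))
            keep[j] = False
        elif not np.isfinite(maf[j]) or maf[j] < maf_min:
            report.snps_removed.append((panel.snp_ids[j], "maf", float(maf[j]) if np.isfinite(maf[j]) else 0.0))
            keep[j] = False
        elif pv[j] < hwe_alpha:
            report.snps_removed.append((panel.snp_ids[j], "hwe", float(pv[j])))
            keep[j] = False
    return panel.subset(snp_idx=np.flatnonzero(keep)), report


def intersect_snps(panels: list[GenotypePanel]) -> GenotypePanel:
    """Merge panels onto the intersection of their SNP sets.

    Animals are concatenated; allele orientation is reconciled against the
    first panel (a swapped allele_a/allele_b flips the dosage 2-g); SNPs with
    irreconcilable allele sets are dropped with a warning.
    """
    if not panels:
        raise PanelError("no panels to intersect")
    common = set(panels[0].snp_ids)
    for pnl in panels[1:]:
        common &= set(pnl.snp_ids)
    order = [s for s in panels[0].snp_ids if s in common]
    ref = panels[0].snp_meta
    dropped: set[str] = set()
    aligned = []
    for pnl in panels:
        idx = [pnl.snp_ids.index(s) for s in order]
        sub = pnl.subset(snp_idx=idx)
        calls = sub.calls.copy()
        for k, s in enumerate(order):
            ra, rb = ref.loc[s, "allele_a"], ref.loc[s, "allele_b"]
            a, b = sub.snp_meta.loc[s, "allele_a"], sub.snp_meta.loc[s, "allele_b"]
            if (a, b) == (ra, rb):
                continue
            if (a, b) == (rb, ra):
                m = calls[:, k] >= 0
                calls[m, k] = 2 - calls[m, k]
            else:
                dropped.add(s)
        aligned.append(calls)
    keep = [k for k, s in enumerate(order) if s not in dropped]
    if dropped:
        warnings.warn(f"{len(dropped)} SNPs dropped: irreconcilable alleles")
    snp_ids = [order[k] for k in keep]
    calls = np.vstack([c[:, keep] for c in aligned])
    animal_ids = sum((p.animal_ids for p in panels), [])
    labels = sum((p.array_labels for p in panels), [])
    return GenotypePanel(animal_ids, snp_ids, calls, labels, ref.loc[snp_ids].copy())


# ---------------------------------------------------------------------------
# parentage
# ---------------------------------------------------------------------------

def count_opposing_homozygotes(g1: np.ndarray, g2: np.ndarray) -> tuple[int, int, float]:
    """Opposing-homozygote count, informative-locus count and rate.

    Loci missing in either vector are excluded from the denominator; a pair
    with no informative loci gets rate 0 with a warning.
    """
    g1 = np.asarray(g1)
    g2 = np.asarray(g2)
    if g1.shape != g2.shape:
        raise PanelError("genotype vectors differ in length")
    both = (g1 >= 0) & (g2 >= 0)
    opp = ((g1 == 0) & (g2 == 2)) | ((g1 == 2) & (g2 == 0))
    n_comp = int(both.sum())
    n_opp = int((opp & both).sum())
    if n_comp == 0:
        warnings.warn("no informative loci shared by the pair; rate set to 0")
        return 0, 0, 0.0
    if n_comp < 100:
        warnings.warn(f"only {n_comp} informative loci for opposing-homozygote test")
    return n_opp, n_comp, n_opp / n_comp


def verify_and_discover_parentage(
    panel: GenotypePanel,
    ped: Pedigree,
    threshold: float = DEFAULT_OH_THRESHOLD,
) -> tuple[Pedigree, QCReport]:
    """Opposing-homozygote parentage verification with discovery.

    For each genotyped animal with a genotyped recorded parent the parent is
    confirmed when the conflicting-SNP rate is at or below ``threshold``;
    otherwise all genotyped candidates of the correct sex born earlier are
    scanned, and the unique best candidate at or below the threshold is
    assigned.  With no qualifying candidate the slot is set to unknown.
    Ungenotyped parents (and animals) are never modified.
    """
    report = QCReport()
    new_ped = ped.copy()
    in_panel = {a: i for i, a in enumerate(panel.animal_ids)}
    hom0 = panel.calls == 0
    hom2 = panel.calls == 2
    nonmiss = panel.calls >= 0

    def oh_rate_many(i: int, rows: np.ndarray) -> np.ndarray:
        opp = (hom0[i] & hom2[rows]) | (hom2[i] & hom0[rows])
        comp = (nonmiss[i] & nonmiss[rows]).sum(axis=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where(comp > 0, opp.sum(axis=1) / np.maximum(comp, 1), 1.0)

    panel_positions = np.array([ped.index[a] for a in panel.animal_ids])
    panel_sex = ped.sex[panel_positions]
    panel_by = ped.birth_year[panel_positions]

    for animal, i in in_panel.items():
        apos = ped.index[animal]
        for slot, want_sex in (("sire", "M"), ("dam", "F")):
            ppos = new_ped.sire[apos] if slot == "sire" else new_ped.dam[apos]
            if ppos < 0:
                continue
            parent = ped.ids[ppos]
            if parent not in in_panel:
                continue
            rate = float(oh_rate_many(i, np.array([in_panel[parent]]))[0])
            if rate <= threshold:
                continue
            # discovery: genotyped candidates, correct sex, born before
            cand = np.flatnonzero(
                (panel_sex == want_sex)
                & (panel_by < ped.birth_year[apos])
                & (panel_positions != apos)
                & (panel_positions != ppos)
            )
            new_parent_pos = -1
            best_rate = np.nan
            if cand.size:
                rates = oh_rate_many(i, cand)
                qual = np.flatnonzero(rates <= threshold)
                if qual.size:
                    order = qual[np.argsort(rates[qual], kind="stable")]
                    best = order[0]
                    unique = qual.size == 1 or rates[order[1]] > rates[best]
                    if unique:
                        new_parent_pos = int(panel_positions[cand[best]])
                        best_rate = float(rates[best])
            if slot == "sire":
                new_ped.sire[apos] = new_parent_pos
            else:
                new_ped.dam[apos] = new_parent_pos
            report.parentage_changes.append(
                (animal, slot, parent,
                 ped.ids[new_parent_pos] if new_parent_pos >= 0 else "0",
                 rate if new_parent_pos < 0 else best_rate)
            )
    return new_ped, report


# ---------------------------------------------------------------------------
# duplicates
# ---------------------------------------------------------------------------

@dataclass
class DuplicateSample:
    """One of several genotype samples for the same animal."""

    calls: np.ndarray
    array_label: str
    parentage_ok: bool
    key: str = ""


def resolve_duplicate_samples(samples: list[DuplicateSample]) -> DuplicateSample:
    """Choose one sample per animal.

    A single parentage-passing sample wins outright; several passing samples
    must be concordant (identical on shared non-missing calls), after which
    the densest-priority array is kept (50K > HD > LDv2 > LDv1), call rate
    breaking ties.  If none passes parentage, the same priority applies to
    all samples.
    """
    if not samples:
        raise ValueError("no samples supplied")
    if len(samples) == 1:
        return samples[0]
    passing = [s for s in samples if s.parentage_ok]
    if len(passing) == 1:
        return passing[0]
    pool = passing if passing else samples
    if len(pool) > 1:
        for a in range(len(pool)):
            for b in range(a + 1, len(pool)):
                g1, g2 = pool[a].calls, pool[b].calls
                both = (g1 >= 0) & (g2 >= 0)
                if np.any(g1[both] != g2[both]):
                    raise DuplicateConflictError(
                        f"discordant duplicate samples ({pool[a].key!r} vs {pool[b].key!r})"
                    )

    def rank(s: DuplicateSample):
        cr = (s.calls >= 0).mean()
        return (ARRAY_PRIORITY.get(s.array_label, 99), -cr)

    return min(pool, key=rank)
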