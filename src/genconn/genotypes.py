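"""Genotype processing for the serotonin-transporter and COMT polymorphisms.

Handles three biallelic markers:

* 5-HTTLPR — the serotonin-transporter promoter length polymorphism with
  short (S) and long (L) alleles.  The low-expressing Lg variant is
  collapsed into S and La into L, so every subject carries one of
  S/S, S/L, L/L.
* COMT rs4680 (Val158Met) — A encodes Met, G encodes Val.
* COMT rs165599 — alleles A and G.

Provides allele-frequency estimation, the 1-df chi-square test of
Hardy-Weinberg equilibrium, an EM haplotype-frequency estimator for the
two COMT markers (with the 0.80 posterior-probability assignment rule),
and deterministic risk-group assignment:

* 5-HTTLPR risk ("S-carrier"): genotype contains at least one S allele.
* COMT risk: rs4680 Val/Val and/or rs165599 A/A.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "BiallelicCounts",
    "GenotypeError",
    "HaplotypePhasing",
    "MARKERS",
    "allele_frequencies",
    "assign_risk_groups",
    "em_phase_two_markers",
    "genotype_counts",
    "hwe_chisq_test",
    "hwe_report",
    "read_genotype_table",
    "parse_genotype_table",
    "round_half_away",
]


class GenotypeError(ValueError):
    """Invalid genotype input (bad category, duplicate subject, empty table)."""


# canonical allele order per marker; the first allele is the one whose
# homozygote count is n_aa in BiallelicCounts (L, Met=A, A respectively)
MARKERS = {
    "httlpr": ("L", "S"),
    "rs4680": ("Met", "Val"),
    "rs165599": ("A", "G"),
}

_ALLELE_SYNONYMS = {
    "httlpr": {"s": "S", "l": "L", "lg": "S", "la": "L"},
    "rs4680": {"met": "Met", "val": "Val", "a": "Met", "g": "Val"},
    "rs165599": {"a": "A", "g": "G"},
}

_MISSING_TOKENS = {"", "na", "nan", "none", "missing", "."}


def round_half_away(x: float, ndigits: int = 2) -> float:
    """Round half away from zero (report convention, unlike banker's rounding)."""
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))


@dataclass(frozen=True)
class BiallelicCounts:
    """Genotype counts at one biallelic marker.

    ``n_aa`` counts first-allele homozygotes, ``n_ab`` heterozygotes and
    ``n_bb`` second-allele homozygotes.
    """

    n_aa: int
    n_ab: int
    n_bb: int

    def __post_init__(self) -> None:
        for name in ("n_aa", "n_ab", "n_bb"):
            v = getattr(self, name)
            if int(v) != v or v < 0:
                raise GenotypeError(f"{name} must be a non-negative integer, got {v!r}")
        if self.n == 0:
            raise GenotypeError("total genotype count must be >= 1")

    @property
    def n(self) -> int:
        return self.n_aa + self.n_ab + self.n_bb


def allele_frequencies(counts: BiallelicCounts) -> tuple[float, float]:
    """Allele frequencies (first allele, second allele) from genotype counts.

    freq_a = (2 n_aa + n_ab) / 2n; the two frequencies sum to 1 exactly.
    """
    n2 = 2 * counts.n
    freq_a = (2 * counts.n_aa + counts.n_ab) / n2
    return freq_a, 1.0 - freq_a


def hwe_chisq_test(counts: BiallelicCounts) -> tuple[float, float]:
    """Chi-square test of Hardy-Weinberg equilibrium with 1 df.

    Expected genotype counts are n*p^2, 2n*p*q, n*q^2 at the observed
    allele frequencies; no continuity correction is applied.  Monomorphic
    samples leave the test undefined.
    """
    p, q = allele_frequencies(counts)
    if p == 0.0 or q == 0.0:
        raise GenotypeError("HWE test undefined for a monomorphic marker")
    n = counts.n
    expected = np.array([n * p * p, 2 * n * p * q, n * q * q])
    observed = np.array([counts.n_aa, counts.n_ab, counts.n_bb], dtype=float)
    statistic = float(np.sum((observed - expected) ** 2 / expected))
    p_value = float(stats.chi2.sf(statistic, df=1))
    return statistic, p_value


# ---------------------------------------------------------------------------
# table parsing


def _normalize_genotype(value: object, marker: str) -> str | None:
    if value is None or (isinstance(value, float) and math.isnan(value)):
        return None
    text = str(value).strip()
    if text.lower() in _MISSING_TOKENS:
        return None
    parts = text.replace("\\", "/").split("/")
    if len(parts) != 2:
        raise GenotypeError(f"cannot parse {marker} genotype {value!r}")
    synonyms = _ALLELE_SYNONYMS[marker]
    try:
        alleles = sorted(
            (synonyms[p.strip().lower()] for p in parts),
            key=MARKERS[marker].index,
        )
    except KeyError as exc:
        raise GenotypeError(f"unknown {marker} allele in {value!r}") from exc
    return "/".join(alleles)


def parse_genotype_table(table: pd.DataFrame) -> pd.DataFrame:
    """Validate and canonicalize a genotype table.

    Expects columns ``subject_id``, ``httlpr``, ``rs4680``, ``rs165599``.
    Genotypes are unordered ("S/L" == "L/S"), case-insensitive; empty
    strings and "NA" mean missing.  Returns a copy with canonical category
    strings (e.g. "S/L", "Val/Met", "A/G") and ``None`` for missing.
    """
    required = ["subject_id", "httlpr", "rs4680", "rs165599"]
    missing_cols = [c for c in required if c not in table.columns]
    if missing_cols:
        raise GenotypeError(f"genotype table missing columns: {missing_cols}")
    out = table.loc[:, required].copy()
    out["subject_id"] = out["subject_id"].astype(str)
    if out["subject_id"].duplicated().any():
        dupes = out.loc[out["subject_id"].duplicated(), "subject_id"].tolist()
        raise GenotypeError(f"duplicate subject ids: {dupes}")
    for marker in MARKERS:
        out[marker] = [_normalize_genotype(v, marker) for v in out[marker]]
    return out


def read_genotype_table(path) -> pd.DataFrame:
    """Read and canonicalize a tab-separated genotype table."""
    raw = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    return parse_genotype_table(raw)


def _allele_dose(genotype: str | None, marker: str) -> int | None:
    """Copies of the marker's first allele (0, 1 or 2); None when missing."""
    if genotype is None:
        return None
    first = MARKERS[marker][0]
    return sum(1 for a in genotype.split("/") if a == first)


def genotype_counts(table: pd.DataFrame, marker: str) -> BiallelicCounts:
    """Genotype counts for one marker from a parsed table (missing dropped)."""
    doses = [_allele_dose(g, marker) for g in table[marker]]
    doses = [d for d in doses if d is not None]
    if not doses:
        raise GenotypeError(f"no genotyped subjects at {marker}")
    return BiallelicCounts(
        n_aa=sum(d == 2 for d in doses),
        n_ab=sum(d == 1 for d in doses),
        n_bb=sum(d == 0 for d in doses),
    )


def hwe_report(table: pd.DataFrame) -> pd.DataFrame:
    """Per-marker genotype counts, allele frequencies and HWE test.

    Frequencies and p-values are also reported rounded to 2 decimals
    (half away from zero), the convention used in cohort tables.
    """
    rows = []
    for marker, (a, b) in MARKERS.items():
        counts = genotype_counts(table, marker)
        fa, fb = allele_frequencies(counts)
        chi2, p = hwe_chisq_test(counts)
        rows.append(
            {
                "marker": marker,
                "n": counts.n,
                "n_aa": counts.n_aa,
                "n_ab": counts.n_ab,
                "n_bb": counts.n_bb,
                "allele_a": a,
                "allele_b": b,
                "freq_a": fa,
                "freq_b": fb,
                "freq_a_2dp": round_half_away(fa),
                "freq_b_2dp": round_half_away(fb),
                "hwe_chi2": chi2,
                "hwe_p": p,
                "hwe_p_2dp": round_half_away(p),
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# two-marker haplotype phasing (EM)

# haplotypes indexed 0..3 as (dose at rs4680, dose at rs165599) where a
# dose of 1 means the marker's first allele (Met resp. A)
_HAPLOTYPES = [(1, 1), (1, 0), (0, 1), (0, 0)]


def haplotype_name(index: int) -> str:
    d1, d2 = _HAPLOTYPES[index]
    return f"{MARKERS['rs4680'][0 if d1 else 1]}-{MARKERS['rs165599'][0 if d2 else 1]}"


@dataclass
class HaplotypePhasing:
    """Result of two-marker EM haplotype phasing.

    ``frequencies`` holds one frequency per haplotype in the order
    Met-A, Met-G, Val-A, Val-G (summing to 1).  ``per_subject`` has one
    row per input subject: the most probable haplotype pair, its
    posterior probability, and the assigned pair (missing when the
    posterior does not exceed ``assign_threshold``).
    """

    frequencies: np.ndarray
    haplotype_names: tuple[str, ...]
    per_subject: pd.DataFrame
    log_likelihood: float
    n_iter: int
    converged: bool
    assign_threshold: float = 0.80
    log_likelihood_trace: list[float] = field(default_factory=list)


def _pair_probability(freqs: np.ndarray, h1: int, h2: int) -> float:
    p = freqs[h1] * freqs[h2]
    return 2.0 * p if h1 != h2 else p


def _compatible_pairs(g1: int, g2: int) -> list[tuple[int, int]]:
    """Unordered haplotype pairs consistent with allele doses (g1, g2)."""
    pairs = []
    for i in range(4):
        for j in range(i, 4):
            a, b = _HAPLOTYPES[i], _HAPLOTYPES[j]
            if a[0] + b[0] == g1 and a[1] + b[1] == g2:
                pairs.append((i, j))
    return pairs


def em_phase_two_markers(
    table: pd.DataFrame,
    max_iter: int = 1000,
    tol: float = 1e-10,
    assign_threshold: float = 0.80,
) -> HaplotypePhasing:
    """Estimate rs4680/rs165599 haplotype frequencies by EM and phase subjects.

    Under random mating the likelihood is multinomial in the four
    haplotype frequencies; only double heterozygotes are phase-ambiguous.
    Frequencies are initialized at linkage equilibrium (products of the
    observed allele frequencies), which is deterministic.  Posterior
    probabilities of compatible haplotype pairs are proportional to the
    product of the pair's haplotype frequencies (times 2 for distinct
    pairs).  A pair is assigned only when its posterior strictly exceeds
    ``assign_threshold``; otherwise the subject's phase is set missing.
    """
    doses = [
        (_allele_dose(g1, "rs4680"), _allele_dose(g2, "rs165599"))
        for g1, g2 in zip(table["rs4680"], table["rs165599"])
    ]
    usable = [(i, d) for i, d in enumerate(doses) if None not in d]
    if not usable:
        raise GenotypeError("no subjects with both COMT markers genotyped")

    # group subjects by genotype class; 9 classes at most
    classes: dict[tuple[int, int], int] = {}
    for _, d in usable:
        classes[d] = classes.get(d, 0) + 1
    class_pairs = {d: _compatible_pairs(*d) for d in classes}

    n_usable = len(usable)
    # linkage-equilibrium initialization from observed allele doses
    p1 = sum(d[0] for _, d in usable) / (2 * n_usable)
    p2 = sum(d[1] for _, d in usable) / (2 * n_usable)
    marg = {1: (p1, p2), 0: (1 - p1, 1 - p2)}
    freqs = np.array([marg[d1][0] * marg[d2][1] for d1, d2 in _HAPLOTYPES])
    # guard against a boundary start when a marker is monomorphic
    if np.any(freqs == 0):
        freqs = (freqs + 1e-12) / (freqs + 1e-12).sum()

    def loglik(f: np.ndarray) -> float:
        ll = 0.0
        for d, count in classes.items():
            prob = sum(_pair_probability(f, i, j) for i, j in class_pairs[d])
            ll += count * math.log(max(prob, 1e-300))
        return ll

    trace = [loglik(freqs)]
    converged = False
    n_iter = 0
    for n_iter in range(1, max_iter + 1):
        expected = np.zeros(4)
        for d, count in classes.items():
            pairs = class_pairs[d]
            weights = np.array([_pair_probability(freqs, i, j) for i, j in pairs])
            weights = weights / weights.sum()
            for (i, j), w in zip(pairs, weights):
                expected[i] += count * w
                expected[j] += count * w
        new_freqs = expected / (2 * n_usable)
        trace.append(loglik(new_freqs))
        if trace[-1] < trace[-2] - 1e-9:  # EM guarantee; numerical slack only
            raise RuntimeError("EM log-likelihood decreased")
        delta = float(np.max(np.abs(new_freqs - freqs)))
        freqs = new_freqs
        if delta < tol:
            converged = True
            break

    # per-subject posteriors and assignment
    names = tuple(haplotype_name(i) for i in range(4))
    records = []
    for idx in range(len(table)):
        d = doses[idx]
        if None in d:
            records.append((table["subject_id"].iloc[idx], None, np.nan, None))
            continue
        pairs = class_pairs[d]
        weights = np.array([_pair_probability(freqs, i, j) for i, j in pairs])
        weights = weights / weights.sum()
        best = int(np.argmax(weights))
        posterior = float(weights[best])
        i, j = pairs[best]
        pair_name = f"{names[i]} | {names[j]}"
        assigned = pair_name if posterior > assign_threshold else None
        records.append((table["subject_id"].iloc[idx], pair_name, posterior, assigned))
    per_subject = pd.DataFrame(
        records, columns=["subject_id", "best_pair", "posterior", "assigned"]
    )
    return HaplotypePhasing(
        frequencies=freqs,
        haplotype_names=names,
        per_subject=per_subject,
        log_likelihood=trace[-1],
        n_iter=n_iter,
        converged=converged,
        assign_threshold=assign_threshold,
        log_likelihood_trace=trace,
    )


# ---------------------------------------------------------------------------
# risk groups

S_CARRIER = "S-carrier"
L_HOMOZYGOTE = "L-homozygote"
COMT_RISK = "risk"
COMT_NON_RISK = "non-risk"


def assign_risk_groups(table: pd.DataFrame) -> pd.DataFrame:
    """Assign each subject to genetic risk / non-risk groups.

    5-HTTLPR: S/S and S/L are S-carriers (risk); L/L is L-homozygote.
    COMT: risk when rs4680 is Val/Val and/or rs165599 is A/A; non-risk
    when both markers are genotyped and neither risk genotype is present.
    A group is missing when the available genotypes cannot decide it.
    """
    httlpr_group = []
    comt_group = []
    for _, row in table.iterrows():
        g = row["httlpr"]
        if g is None:
            httlpr_group.append(None)
        else:
            httlpr_group.append(S_CARRIER if "S" in g.split("/") else L_HOMOZYGOTE)

        r4680, r165599 = row["rs4680"], row["rs165599"]
        risk_4680 = None if r4680 is None else (r4680 == "Val/Val")
        risk_165599 = None if r165599 is None else (r165599 == "A/A")
        if risk_4680 or risk_165599:
            comt_group.append(COMT_RISK)
        elif risk_4680 is False and risk_165599 is False:
            comt_group.append(COMT_NON_RISK)
        else:
            comt_group.append(None)
    out = table[["subject_id"]].copy()
    out["httlpr_group"] = httlpr_group
    out["comt_group"] = comt_group
    return out
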