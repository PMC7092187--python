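"""Immunoediting statistics at allele, variant, patient and histology level.

The estimand throughout is an observed:expected ratio. Under no immunoediting
a patient's HLA genotype is independent of which variants their tumor
harbors, so:

* **allele level** — among the unique patients harboring >= 1 variant strongly
  bound by an allele, the fraction carrying that allele should equal the
  population carrier frequency ``1 - (1 - f)^2``.  A deficit (ratio < 1)
  indicates that clones presenting those variants were eliminated in carriers.
* **variant level** — across a variant's ``n`` occurrences, the number of
  occurrences in patients carrying any of the variant's binding alleles should
  be ``n * p_v`` with ``p_v`` the variant's population carrier probability;
  observing zero has probability ``(1 - p_v)^n``.
* **patient / histology level** — summing each harbored variant's carrier
  probability gives the expected number of presentable variants; the observed
  count follows a Poisson-binomial distribution under the null, whose exact
  lower tail is computed by dynamic-programming convolution.

One-sided exact binomial tests are used at allele and variant level,
Poisson-binomial lower tails at patient/histology level, Benjamini-Hochberg
for FDR, and Welch's t on log affinities for comparing allele groups.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .presentation import AlleleFrequencyTable, PresentationMap, carrier_probability
from .windows import PeptideWindow

ANCHOR_OFFSETS = frozenset({2, 9})
LOCUS_COLUMNS = ["A1", "A2", "B1", "B2", "C1", "C2"]


class CohortError(ValueError):
    pass


class CohortTable:
    """A cancer cohort: patient genotypes, histologies and harbored variants.

    ``patients`` has columns patient_id, histology, A1, A2, B1, B2, C1, C2
    (six class I alleles; homozygosity allowed).  ``membership`` has one row
    per (patient_id, variant_id) occurrence.
    """

    def __init__(self, patients: pd.DataFrame, membership: pd.DataFrame):
        required = ["patient_id", "histology", *LOCUS_COLUMNS]
        missing = [c for c in required if c not in patients.columns]
        if missing:
            raise CohortError(f"patients table missing columns {missing}")
        if patients["patient_id"].duplicated().any():
            raise CohortError("duplicate patient ids")
        self.patients = patients[required].reset_index(drop=True)
        self.membership = membership[["patient_id", "variant_id"]].reset_index(drop=True)
        unknown = set(self.membership["patient_id"]) - set(self.patients["patient_id"])
        if unknown:
            raise CohortError(f"membership references unknown patients: {sorted(unknown)[:5]}")
        self._genotypes = {
            row.patient_id: frozenset(getattr(row, c) for c in LOCUS_COLUMNS)
            for row in self.patients.itertuples()
        }

    @property
    def n_patients(self) -> int:
        return len(self.patients)

    @property
    def patient_ids(self) -> list[str]:
        return self.patients["patient_id"].tolist()

    @property
    def histologies(self) -> list[str]:
        return sorted(self.patients["histology"].unique())

    def genotype(self, patient_id: str) -> frozenset:
        try:
            return self._genotypes[patient_id]
        except KeyError:
            raise CohortError(f"unknown patient {patient_id!r}") from None

    def histology_of(self, patient_id: str) -> str:
        row = self.patients.loc[self.patients["patient_id"] == patient_id, "histology"]
        if row.empty:
            raise CohortError(f"unknown patient {patient_id!r}")
        return str(row.iloc[0])

    def variants_of(self, patient_id: str) -> list[str]:
        m = self.membership
        return m.loc[m["patient_id"] == patient_id, "variant_id"].unique().tolist()

    def patients_with(self, variant_ids: Iterable[str]) -> list[str]:
        """Unique patients harboring at least one of the given variants."""
        wanted = set(variant_ids)
        m = self.membership
        return m.loc[m["variant_id"].isin(wanted), "patient_id"].unique().tolist()

    def occurrences_of(self, variant_id: str) -> list[str]:
        """Patient ids of all occurrences of one variant (unique patients)."""
        m = self.membership
        return m.loc[m["variant_id"] == variant_id, "patient_id"].unique().tolist()


@dataclass
class EditingResult:
    """Observed-vs-expected immunoediting statistics for one analysis unit."""

    unit: str
    level: str  # allele | variant | patient | histology
    n: int
    expected: float
    observed: float
    ratio: float
    p: float
    q: float | None = None
    note: str | None = None

    @property
    def tested(self) -> bool:
        return self.note is None

    def to_dict(self) -> dict:
        return {
            "unit": self.unit,
            "level": self.level,
            "n": self.n,
            "expected": self.expected,
            "observed": self.observed,
            "ratio": self.ratio,
            "p": self.p,
            "q": self.q,
            "note": self.note,
        }


# ---------------------------------------------------------------------------
# exact distributions


def poisson_binomial_pmf(probs: Sequence[float]) -> np.ndarray:
    """Exact pmf of a sum of independent Bernoulli(p_i) by DP convolution.

    Returns an array of length ``len(probs) + 1``; entry k is P(X = k).
    """
    probs = np.asarray(probs, dtype=float)
    if probs.size and (probs.min() < 0 or probs.max() > 1):
        raise ValueError("probabilities must lie in [0, 1]")
    pmf = np.ones(1)
    for p in probs:
        pmf = np.convolve(pmf, [1.0 - p, p])
    return pmf


def poisson_binomial_cdf(k: int, probs: Sequence[float]) -> float:
    """P(X <= k) for the Poisson-binomial sum of Bernoulli(p_i)."""
    if k < 0:
        return 0.0
    pmf = poisson_binomial_pmf(probs)
    return float(min(1.0, pmf[: int(k) + 1].sum()))


def fdr_adjust(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    return multipletests(p, method="fdr_bh")[1]


def _binom_lower_p(observed: int, n: int, prob: float) -> float:
    """One-sided exact binomial p-value, alternative 'fewer than expected'."""
    return float(stats.binom.cdf(observed, n, prob))


# ---------------------------------------------------------------------------
# allele level


def allele_editing(
    cohort: CohortTable,
    pmap: PresentationMap,
    freqs: AlleleFrequencyTable,
    allele: str,
    mode: str = "carrier",
) -> EditingResult:
    """Observed vs expected frequency of one allele among binder-harboring patients.

    The eligible set is the unique patients harboring >= 1 variant whose
    strong-binding allele set contains ``allele``.  In the default ``carrier``
    mode, observed is the number of eligible patients with >= 1 copy and the
    expectation is the HWE carrier frequency ``1 - (1 - f)^2``; ``allelic``
    mode counts copies out of ``2n`` with expectation ``f``.
    """
    bound_variants = [v for v, s in pmap.binding_sets.items() if allele in s]
    eligible = cohort.patients_with(bound_variants)
    n = len(eligible)
    f = freqs.frequency(allele)
    if n == 0:
        return EditingResult(
            unit=allele, level="allele", n=0, expected=np.nan, observed=np.nan,
            ratio=np.nan, p=np.nan, note="no patients harbor a variant bound by this allele",
        )
    if mode == "carrier":
        expected_freq = 1.0 - (1.0 - f) ** 2
        observed = sum(1 for pid in eligible if allele in cohort.genotype(pid))
        trials = n
    elif mode == "allelic":
        expected_freq = f
        counts = []
        for pid in eligible:
            row = cohort.patients.loc[cohort.patients["patient_id"] == pid].iloc[0]
            counts.append(sum(row[c] == allele for c in LOCUS_COLUMNS))
        observed = int(sum(counts))
        trials = 2 * n
    else:
        raise ValueError(f"unknown mode {mode!r}")
    observed_freq = observed / trials
    ratio = observed_freq / expected_freq if expected_freq > 0 else np.nan
    p = _binom_lower_p(observed, trials, expected_freq)
    return EditingResult(
        unit=allele, level="allele", n=n,
        expected=expected_freq, observed=observed_freq, ratio=ratio, p=p,
    )


def allele_editing_table(
    cohort: CohortTable,
    pmap: PresentationMap,
    freqs: AlleleFrequencyTable,
    alleles: Sequence[str] | None = None,
    min_allele_freq: float = 0.05,
    mode: str = "carrier",
) -> pd.DataFrame:
    """Allele-level editing results with BH-adjusted q-values.

    By default tests all panel alleles with population frequency above
    ``min_allele_freq`` (the analysis is powered only for common alleles).
    """
    if alleles is None:
        alleles = [a for a in freqs.alleles if freqs.frequency(a) > min_allele_freq]
    results = [allele_editing(cohort, pmap, freqs, a, mode) for a in alleles]
    frame = pd.DataFrame([r.to_dict() for r in results])
    frame["q"] = np.nan
    tested = frame["note"].isna()
    if tested.any():
        frame.loc[tested, "q"] = fdr_adjust(frame.loc[tested, "p"].to_numpy())
    return frame


def editing_scores(
    results: pd.DataFrame,
    breadths: Mapping[str, float] | pd.Series,
    freqs: AlleleFrequencyTable,
) -> pd.DataFrame:
    """Composite per-allele immunoediting scores, ranked descending.

    underrepresentation = max(0, 1 - observed:expected ratio);
    editing_score = breadth x underrepresentation (breadth is the fraction of
    neoantigens the allele binds strongly); population_contribution =
    editing_score x population allele frequency.
    """
    rows = []
    for r in results.itertuples():
        if "note" in results.columns and isinstance(r.note, str):
            continue
        under = max(0.0, 1.0 - r.ratio) if np.isfinite(r.ratio) else np.nan
        breadth = float(breadths[r.unit])
        score = breadth * under if np.isfinite(under) else np.nan
        freq = freqs.frequency(r.unit)
        rows.append((r.unit, breadth, under, score, freq, score * freq if np.isfinite(score) else np.nan))
    out = pd.DataFrame(
        rows,
        columns=[
            "allele", "breadth", "underrepresentation", "editing_score",
            "frequency", "population_contribution",
        ],
    )
    return out.sort_values("editing_score", ascending=False, kind="mergesort").reset_index(drop=True)


# ---------------------------------------------------------------------------
# variant level


def variant_editing(
    variant_id: str,
    cohort: CohortTable,
    pmap: PresentationMap,
    freqs: AlleleFrequencyTable,
    mode: str = "diploid",
) -> EditingResult:
    """Zero-or-few-carrier test for one variant across its occurrences.

    With per-occurrence carrier probability ``p_v`` (the probability a random
    patient carries >= 1 allele binding the variant) and ``n`` occurrences,
    tests whether the observed number of binder-carrying occurrences is lower
    than the binomial expectation ``n * p_v``.  For observed = 0 the p-value
    is exactly ``(1 - p_v)^n``.
    """
    occurrences = cohort.occurrences_of(variant_id)
    n = len(occurrences)
    if n == 0:
        raise CohortError(f"variant {variant_id!r} has no occurrences in the cohort")
    binding = pmap.binding_sets.get(variant_id)
    if binding is None:
        raise CohortError(f"variant {variant_id!r} not in presentation map")
    p_v = carrier_probability(binding, freqs, mode)
    if not binding:
        return EditingResult(
            unit=variant_id, level="variant", n=n, expected=0.0, observed=0.0,
            ratio=np.nan, p=np.nan, note="immunogenically silent; test skipped",
        )
    observed = sum(1 for pid in occurrences if cohort.genotype(pid) & binding)
    expected = n * p_v
    ratio = observed / expected if expected > 0 else np.nan
    p = _binom_lower_p(observed, n, p_v)
    return EditingResult(
        unit=variant_id, level="variant", n=n,
        expected=expected, observed=float(observed), ratio=ratio, p=p,
    )


# ---------------------------------------------------------------------------
# patient and histology level


def _patient_probs_observed(
    patient_id: str,
    cohort: CohortTable,
    pmap: PresentationMap,
    freqs: AlleleFrequencyTable,
    mode: str = "diploid",
) -> tuple[list[float], int]:
    genotype = cohort.genotype(patient_id)
    probs: list[float] = []
    observed = 0
    for vid in cohort.variants_of(patient_id):
        binding = pmap.binding_sets.get(vid)
        if binding is None:
            raise CohortError(f"variant {vid!r} not in presentation map")
        if not binding:
            continue  # silent variants carry no information here
        probs.append(carrier_probability(binding, freqs, mode))
        if genotype & binding:
            observed += 1
    return probs, observed


def patient_editing(
    patient_id: str,
    cohort: CohortTable,
    pmap: PresentationMap,
    freqs: AlleleFrequencyTable,
    mode: str = "diploid",
) -> EditingResult:
    """Depletion of presentable variants in one patient vs the null expectation.

    Expected = sum of carrier probabilities over the patient's non-silent
    variants; observed = how many of those variants the patient's own genotype
    can present; p-value from the exact Poisson-binomial lower tail.
    """
    probs, observed = _patient_probs_observed(patient_id, cohort, pmap, freqs, mode)
    if not probs:
        return EditingResult(
            unit=patient_id, level="patient", n=0, expected=0.0, observed=0.0,
            ratio=np.nan, p=np.nan, note="only silent variants; no test",
        )
    expected = float(np.sum(probs))
    ratio = observed / expected if expected > 0 else np.nan
    p = poisson_binomial_cdf(observed, probs)
    return EditingResult(
        unit=patient_id, level="patient", n=len(probs),
        expected=expected, observed=float(observed), ratio=ratio, p=p,
    )


def histology_editing(
    cohort: CohortTable,
    histology: str,
    pmap: PresentationMap,
    freqs: AlleleFrequencyTable,
    mode: str = "diploid",
) -> EditingResult:
    """Pooled patient-level depletion test across one histology.

    Expected and observed counts are summed over the histology's patients and
    the pooled Poisson-binomial lower tail gives the p-value; a single-patient
    histology reduces to that patient's test.
    """
    pts = cohort.patients.loc[
        cohort.patients["histology"] == histology, "patient_id"
    ].tolist()
    if not pts:
        raise CohortError(f"no patients with histology {histology!r}")
    probs: list[float] = []
    observed = 0
    for pid in pts:
        p_i, obs_i = _patient_probs_observed(pid, cohort, pmap, freqs, mode)
        probs.extend(p_i)
        observed += obs_i
    if not probs:
        return EditingResult(
            unit=histology, level="histology", n=len(pts), expected=0.0,
            observed=0.0, ratio=np.nan, p=np.nan,
            note="only silent variants; no test",
        )
    expected = float(np.sum(probs))
    ratio = observed / expected if expected > 0 else np.nan
    p = poisson_binomial_cdf(observed, probs)
    return EditingResult(
        unit=histology, level="histology", n=len(pts),
        expected=expected, observed=float(observed), ratio=ratio, p=p,
    )


# ---------------------------------------------------------------------------
# silence enrichment, anchor groups, affinity comparison


def silent_enrichment(
    cohort: CohortTable, pmap: PresentationMap
) -> tuple[float, float, float]:
    """Are silent variants over-represented among observed tumor mutations?

    Returns (observed fraction of occurrences that are silent, baseline
    fraction of characterised variants that are silent, one-sided binomial p
    for enrichment).  When no variant is silent the test is skipped (p NaN).
    """
    silent = set(pmap.frame.index[pmap.frame["silent"]])
    baseline = pmap.silent_fraction()
    m = cohort.membership
    total = len(m)
    silent_occ = int(m["variant_id"].isin(silent).sum())
    observed = silent_occ / total if total else np.nan
    if not silent or total == 0:
        return observed, baseline, np.nan
    p = float(stats.binomtest(silent_occ, total, baseline, alternative="greater").pvalue)
    return observed, baseline, p


def classify_group(window: PeptideWindow | int) -> int:
    """Anchor classification: group 2 if the mutation hits peptide position
    2 or 9 (the HLA-facing anchors), else group 1 (TCR-facing)."""
    offset = window.offset if isinstance(window, PeptideWindow) else int(window)
    if not 1 <= offset <= 9:
        raise ValueError(f"offset {offset} outside 1..9")
    return 2 if offset in ANCHOR_OFFSETS else 1


def affinity_comparison(
    editing_alleles: Sequence[str],
    non_editing_alleles: Sequence[str],
    summaries: pd.DataFrame,
) -> tuple[float, float, float]:
    """Compare strong-binder affinities between two allele groups.

    Returns (mean nM in the editing group, mean nM in the non-editing group,
    two-sided Welch-t p-value computed on log affinities — affinities are
    log-normal-ish, so the test is run on the log scale while means are
    reported on the nM scale).
    """
    strong = summaries[summaries["strong"]]
    g1 = strong.loc[strong["allele"].isin(set(editing_alleles)), "best_affinity"]
    g2 = strong.loc[strong["allele"].isin(set(non_editing_alleles)), "best_affinity"]
    if g1.empty or g2.empty:
        raise ValueError("both allele groups need at least one strong binder")
    stat = stats.ttest_ind(np.log(g1), np.log(g2), equal_var=False)
    return float(g1.mean()), float(g2.mean()), float(stat.pvalue)
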