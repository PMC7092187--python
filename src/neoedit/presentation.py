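"""Population-scale presentation: carrier probabilities and regional profiles.

The population carrier probability of an allele set is the chance that a
random diploid individual carries at least one allele from the set, under
Hardy-Weinberg equilibrium within each class I locus (A, B, C) and
independence between loci: with ``f_L`` the summed frequency of the set's
alleles at locus ``L``,

    P(carrier) = 1 - prod_L (1 - f_L)^2.

Linkage between loci is disregarded, which slightly underestimates expected
carrier frequencies and therefore biases downstream immunoediting estimates
toward the conservative side.

A variant is *immunogenically silent* when none of its 9-mer windows is a
strong binder for any allele in the panel; its carrier probability is zero.

Regional profiles score each protein position by the fraction of the
population presenting at least one 9-mer window containing it (the union of
the windows' strong-binding allele sets), suitable for overlaying mutation
hotspots and ranking vaccine-candidate regions.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .binding import STRONG_RANK_THRESHOLD, _normalize_allele
from .windows import EPITOPE_LENGTH, ProteinRecord, window_starts

LOCI = ("A", "B", "C")


class FrequencyTableError(ValueError):
    pass


class AlleleFrequencyTable:
    """Per-locus class I allele population frequencies.

    Wraps a DataFrame with columns allele, locus, frequency; alleles must be
    unique and per-locus frequency sums must not exceed 1.
    """

    def __init__(self, table: pd.DataFrame):
        required = ["allele", "locus", "frequency"]
        missing = [c for c in required if c not in table.columns]
        if missing:
            raise FrequencyTableError(f"missing columns {missing}")
        table = table[required].copy()
        table["allele"] = table["allele"].map(_normalize_allele)
        table["locus"] = table["locus"].astype(str).str.upper()
        table["frequency"] = table["frequency"].astype(float)
        if table["allele"].duplicated().any():
            dup = table.loc[table["allele"].duplicated(), "allele"].tolist()
            raise FrequencyTableError(f"duplicate alleles: {dup}")
        bad_locus = set(table["locus"]) - set(LOCI)
        if bad_locus:
            raise FrequencyTableError(f"unknown loci: {sorted(bad_locus)}")
        if (table["frequency"] < 0).any() or (table["frequency"] > 1).any():
            raise FrequencyTableError("frequencies must lie in [0, 1]")
        sums = table.groupby("locus")["frequency"].sum()
        over = sums[sums > 1 + 1e-9]
        if not over.empty:
            raise FrequencyTableError(
                f"per-locus frequency sums exceed 1: {over.to_dict()}"
            )
        self.table = table.reset_index(drop=True)
        self._freq = dict(zip(table["allele"], table["frequency"]))
        self._locus = dict(zip(table["allele"], table["locus"]))

    @classmethod
    def from_tsv(cls, path: str | Path) -> "AlleleFrequencyTable":
        return cls(pd.read_csv(path, sep="\t"))

    def to_tsv(self, path: str | Path) -> None:
        self.table.to_csv(path, sep="\t", index=False)

    @property
    def alleles(self) -> list[str]:
        return self.table["allele"].tolist()

    def __contains__(self, allele: str) -> bool:
        return allele in self._freq

    def frequency(self, allele: str) -> float:
        try:
            return self._freq[allele]
        except KeyError:
            raise FrequencyTableError(f"allele {allele!r} not in frequency table") from None

    def locus(self, allele: str) -> str:
        try:
            return self._locus[allele]
        except KeyError:
            raise FrequencyTableError(f"allele {allele!r} not in frequency table") from None

    def carrier_frequency(self, allele: str) -> float:
        """Population fraction carrying >= 1 copy: 1 - (1 - f)^2 under HWE."""
        f = self.frequency(allele)
        return 1.0 - (1.0 - f) ** 2


def carrier_probability(
    binding_alleles: Iterable[str],
    freqs: AlleleFrequencyTable,
    mode: str = "diploid",
) -> float:
    """Probability a random individual carries >= 1 allele from the set.

    ``mode='diploid'`` (default) uses the HWE two-draws-per-locus model
    ``1 - prod_L (1 - f_L)^2``; ``mode='allelic'`` uses the simpler
    single-draw union ``1 - prod_a (1 - f_a)``.
    """
    alleles = set(binding_alleles)
    if not alleles:
        return 0.0
    if mode == "allelic":
        p_none = 1.0
        for a in alleles:
            p_none *= 1.0 - freqs.frequency(a)
        return 1.0 - p_none
    if mode != "diploid":
        raise ValueError(f"unknown mode {mode!r}")
    locus_sum: dict[str, float] = {}
    for a in alleles:
        locus_sum[freqs.locus(a)] = locus_sum.get(freqs.locus(a), 0.0) + freqs.frequency(a)
    p_none = 1.0
    for f_l in locus_sum.values():
        if f_l > 1 + 1e-9:
            raise FrequencyTableError(f"locus frequency sum {f_l} exceeds 1")
        p_none *= (1.0 - min(f_l, 1.0)) ** 2
    return 1.0 - p_none


@dataclass
class PresentationMap:
    """Per-variant strong-binding allele sets with population carrier view.

    ``binding_sets`` maps variant_id -> frozenset of strong-binding alleles;
    ``frame`` indexes variant_id with columns n_alleles, carrier_prob, silent.
    A variant is silent iff its allele set is empty, iff carrier_prob is 0.
    """

    binding_sets: dict[str, frozenset]
    frame: pd.DataFrame

    @classmethod
    def from_sets(
        cls,
        binding_sets: Mapping[str, Iterable[str]],
        freqs: AlleleFrequencyTable,
        mode: str = "diploid",
    ) -> "PresentationMap":
        sets = {v: frozenset(s) for v, s in binding_sets.items()}
        frame = pd.DataFrame(
            {
                "n_alleles": [len(s) for s in sets.values()],
                "carrier_prob": [carrier_probability(s, freqs, mode) for s in sets.values()],
            },
            index=pd.Index(list(sets), name="variant_id"),
        )
        frame["silent"] = frame["n_alleles"] == 0
        return cls(binding_sets=sets, frame=frame)

    @classmethod
    def from_summaries(
        cls,
        summaries: pd.DataFrame,
        freqs: AlleleFrequencyTable,
        panel: Sequence[str] | None = None,
        mode: str = "diploid",
    ) -> "PresentationMap":
        """Build from a complete variant x allele summary grid.

        Raises when the grid is incomplete (every variant must have a summary
        row for every panel allele).
        """
        if panel is None:
            panel = sorted(summaries["allele"].unique())
        n_variants = summaries["variant_id"].nunique()
        if len(summaries) != n_variants * len(panel):
            raise ValueError(
                f"incomplete summary grid: {len(summaries)} rows for "
                f"{n_variants} variants x {len(panel)} alleles"
            )
        strong = summaries[summaries["strong"]]
        sets = strong.groupby("variant_id")["allele"].agg(frozenset).to_dict()
        all_sets = {
            v: sets.get(v, frozenset()) for v in summaries["variant_id"].unique()
        }
        return cls.from_sets(all_sets, freqs, mode)

    @property
    def variant_ids(self) -> list[str]:
        return list(self.frame.index)

    def carrier_prob(self, variant_id: str) -> float:
        return float(self.frame.loc[variant_id, "carrier_prob"])

    def is_silent(self, variant_id: str) -> bool:
        return bool(self.frame.loc[variant_id, "silent"])

    def silent_fraction(self) -> float:
        """Fraction of characterised variants that are immunogenically silent."""
        return float(self.frame["silent"].mean())

    def to_frame(self) -> pd.DataFrame:
        out = self.frame.copy()
        out["alleles"] = [
            ";".join(sorted(self.binding_sets[v])) for v in out.index
        ]
        return out.reset_index()


def call_silent(
    summaries: pd.DataFrame,
    freqs: AlleleFrequencyTable,
    panel: Sequence[str] | None = None,
    mode: str = "diploid",
) -> PresentationMap:
    """Presentation map with silence calls from a complete summary grid."""
    return PresentationMap.from_summaries(summaries, freqs, panel, mode)


def allele_breadth(summaries: pd.DataFrame, allele: str) -> float:
    """Fraction of variants whose best window is a strong binder at ``allele``."""
    sub = summaries[summaries["allele"] == allele]
    if sub.empty:
        raise ValueError(f"allele {allele!r} not in summaries")
    return float(sub["strong"].mean())


def breadth_table(summaries: pd.DataFrame) -> pd.Series:
    """Per-allele fraction of variants bound strongly (Fig-2C-style breadth)."""
    return summaries.groupby("allele")["strong"].mean()


def strong_pair_fraction(summaries: pd.DataFrame) -> float:
    """Fraction of aggregated (variant, allele) pairs that are strong binders."""
    return float(summaries["strong"].mean())


# ---------------------------------------------------------------------------
# regional profiles


@dataclass
class RegionalProfile:
    """Per-position presentation profile of one protein.

    ``frame`` has one row per residue with columns position (1-based),
    positional_score (carrier probability of the 9-mer *starting* there; NaN
    for the last eight residues), regional_score (carrier probability of the
    union over all 9-mers *containing* the residue) and n_alleles (size of
    that union).  ``window_sets`` maps window start -> strong allele set.
    """

    protein_id: str
    length: int
    frame: pd.DataFrame
    window_sets: dict[int, frozenset]
    region_sets: dict[int, frozenset]


def _window_strong_sets(
    protein: ProteinRecord,
    predictor,
    threshold: float = STRONG_RANK_THRESHOLD,
    panel: Sequence[str] | None = None,
) -> dict[int, frozenset]:
    """Strong-binding allele set of the wild-type 9-mer at each start."""
    length = len(protein)
    starts = list(range(1, length - EPITOPE_LENGTH + 2))
    peptides = [protein.sequence[s - 1 : s - 1 + EPITOPE_LENGTH] for s in starts]
    records = predictor.predict(peptides, panel)
    strong = records[records["percent_rank"] <= threshold]
    by_pep = strong.groupby("peptide")["allele"].agg(frozenset).to_dict()
    return {s: by_pep.get(p, frozenset()) for s, p in zip(starts, peptides)}


def positional_score(
    protein: ProteinRecord,
    start: int,
    predictor,
    freqs: AlleleFrequencyTable,
    threshold: float = STRONG_RANK_THRESHOLD,
    panel: Sequence[str] | None = None,
    mode: str = "diploid",
) -> float:
    """Population fraction presenting the wild-type 9-mer starting at ``start``."""
    if not 1 <= start <= len(protein) - EPITOPE_LENGTH + 1:
        raise ValueError(f"start {start} out of range for length {len(protein)}")
    peptide = protein.sequence[start - 1 : start - 1 + EPITOPE_LENGTH]
    records = predictor.predict([peptide], panel)
    alleles = records.loc[records["percent_rank"] <= threshold, "allele"]
    return carrier_probability(alleles, freqs, mode)


def regional_score(
    protein: ProteinRecord,
    position: int,
    predictor,
    freqs: AlleleFrequencyTable,
    threshold: float = STRONG_RANK_THRESHOLD,
    panel: Sequence[str] | None = None,
    mode: str = "diploid",
    combine: str = "union",
) -> float:
    """Population fraction presenting >= 1 of the 9-mers containing ``position``.

    ``combine='union'`` (default) takes the carrier probability of the union
    of the covering windows' strong allele sets; ``combine='mean'`` averages
    the covering windows' positional scores (sensitivity alternative).
    """
    if not 1 <= position <= len(protein):
        raise ValueError(f"position {position} out of range")
    sets = _window_strong_sets(protein, predictor, threshold, panel)
    covering = [sets[s] for s in window_starts(position, len(protein))]
    if combine == "mean":
        return float(
            np.mean([carrier_probability(s, freqs, mode) for s in covering])
        )
    if combine != "union":
        raise ValueError(f"unknown combine {combine!r}")
    union: frozenset = frozenset().union(*covering)
    return carrier_probability(union, freqs, mode)


def compute_profile(
    protein: ProteinRecord,
    predictor,
    freqs: AlleleFrequencyTable,
    threshold: float = STRONG_RANK_THRESHOLD,
    panel: Sequence[str] | None = None,
    mode: str = "diploid",
    mask: tuple[int, int] | None = None,
    combine: str = "union",
) -> RegionalProfile:
    """Full per-residue presentation profile of a protein.

    ``mask`` is an optional inclusive 1-based residue range (e.g. a cleaved
    signal peptide) whose positions get NaN scores in the output frame.
    """
    length = len(protein)
    sets = _window_strong_sets(protein, predictor, threshold, panel)
    pos_scores = {s: carrier_probability(a, freqs, mode) for s, a in sets.items()}
    rows = []
    region_sets: dict[int, frozenset] = {}
    for pos in range(1, length + 1):
        covering = [sets[s] for s in window_starts(pos, length)]
        union: frozenset = frozenset().union(*covering) if covering else frozenset()
        region_sets[pos] = union
        if combine == "mean":
            reg = float(np.mean([carrier_probability(s, freqs, mode) for s in covering]))
        else:
            reg = carrier_probability(union, freqs, mode)
        rows.append((pos, pos_scores.get(pos, np.nan), reg, len(union)))
    frame = pd.DataFrame(
        rows, columns=["position", "positional_score", "regional_score", "n_alleles"]
    )
    if mask is not None:
        lo, hi = mask
        in_mask = (frame["position"] >= lo) & (frame["position"] <= hi)
        frame.loc[in_mask, ["positional_score", "regional_score"]] = np.nan
    return RegionalProfile(
        protein_id=protein.id,
        length=length,
        frame=frame,
        window_sets=sets,
        region_sets=region_sets,
    )


def tile_regions(
    protein: ProteinRecord,
    k: int,
    predictor,
    freqs: AlleleFrequencyTable,
    threshold: float = STRONG_RANK_THRESHOLD,
    panel: Sequence[str] | None = None,
    mode: str = "diploid",
) -> pd.DataFrame:
    """Rank k-mer regions by the population fraction presenting any sub-9-mer.

    For every region of length ``k`` (k >= 9, k <= protein length) the strong
    allele sets of all 9-mers fully inside the region are unioned; regions are
    ranked by carrier probability (descending), ties broken by more alleles
    then lower start.  Columns: start, end, sequence, n_alleles, alleles,
    carrier_prob.
    """
    length = len(protein)
    if k < EPITOPE_LENGTH:
        raise ValueError(f"k must be >= {EPITOPE_LENGTH}, got {k}")
    if k > length:
        raise ValueError(f"k={k} exceeds protein length {length}")
    sets = _window_strong_sets(protein, predictor, threshold, panel)
    rows = []
    for start in range(1, length - k + 2):
        inner = [sets[s] for s in range(start, start + k - EPITOPE_LENGTH + 1)]
        union: frozenset = frozenset().union(*inner)
        rows.append(
            (
                start,
                start + k - 1,
                protein.sequence[start - 1 : start - 1 + k],
                len(union),
                ";".join(sorted(union)),
                carrier_probability(union, freqs, mode),
            )
        )
    out = pd.DataFrame(
        rows, columns=["start", "end", "sequence", "n_alleles", "alleles", "carrier_prob"]
    )
    out = out.sort_values(
        ["carrier_prob", "n_alleles", "start"], ascending=[False, False, True],
        kind="mergesort",
    ).reset_index(drop=True)
    return out


def ligandome_concordance(
    detected_peptides: Sequence[tuple[str, int]],
    profiles: Mapping[str, RegionalProfile] | RegionalProfile,
    n_permutations: int = 9999,
    seed: int | None = None,
) -> tuple[float, float]:
    """Permutation test: are detected ligands enriched in high-scoring regions?

    ``detected_peptides`` are (protein_id, position) anchor positions of
    mass-spectrometry-detected ligands; duplicates count once.  The statistic
    is the mean regional score at the detected positions; the null draws
    position sets of equal size uniformly (without replacement) from all
    positions with a defined regional score, and the p-value uses the
    add-one correction (r + 1) / (n + 1).
    """
    if isinstance(profiles, RegionalProfile):
        profiles = {profiles.protein_id: profiles}
    scores = []
    eligible = []
    for pid, prof in profiles.items():
        s = prof.frame.set_index("position")["regional_score"]
        s = s.dropna()
        eligible.append(s.to_numpy())
    pool = np.concatenate(eligible)
    seen = set()
    for pid, pos in detected_peptides:
        if pid not in profiles:
            warnings.warn(f"detected peptide on unprofiled protein {pid!r}; skipped")
            continue
        if (pid, pos) in seen:
            continue
        seen.add((pid, pos))
        s = profiles[pid].frame.set_index("position")["regional_score"]
        val = s.get(pos, np.nan)
        if np.isnan(val):
            warnings.warn(f"position {pos} of {pid!r} has no defined score; skipped")
            continue
        scores.append(float(val))
    if not scores:
        raise ValueError("no detected peptides map onto profiled proteins")
    m = len(scores)
    statistic = float(np.mean(scores))
    rng = np.random.default_rng(seed)
    null = np.empty(n_permutations)
    for i in range(n_permutations):
        null[i] = pool[rng.choice(pool.size, size=m, replace=False)].mean()
    r = int(np.sum(null >= statistic))
    p = (r + 1) / (n_permutations + 1)
    return statistic, p


def patients_with_silent_fraction(cohort, pmap: PresentationMap) -> float:
    """Fraction of cohort patients harboring >= 1 immunogenically silent variant."""
    silent = set(pmap.frame.index[pmap.frame["silent"]])
    members = cohort.membership
    with_silent = members.loc[members["variant_id"].isin(silent), "patient_id"].nunique()
    return with_silent / cohort.n_patients


def plot_regional_profile(
    profile: RegionalProfile,
    mutation_counts: Mapping[int, int] | None = None,
    ax=None,
):
    """Bar plot of regional scores with an optional mutation lollipop overlay."""
    import matplotlib

    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(10, 3))
    f = profile.frame
    ax.bar(f["position"], f["regional_score"], width=1.0, color="0.6", label="regional score")
    ax.set_xlabel(f"{profile.protein_id} residue")
    ax.set_ylabel("population fraction presenting")
    ax.set_ylim(0, 1.05)
    if mutation_counts:
        ax2 = ax.twinx()
        pos = sorted(mutation_counts)
        counts = [mutation_counts[p] for p in pos]
        ax2.stem(pos, counts, linefmt="g-", markerfmt="go", basefmt=" ")
        ax2.set_ylabel("mutation count", color="g")
    return ax
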