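"""MHC class I binding prediction contract and per-variant aggregation.

Any object mapping ``(peptides, alleles) -> DataFrame`` of binding records can
drive the pipeline.  Two implementations are provided:

* :class:`MotifPredictor` — a deterministic synthetic predictor that scores a
  9-mer as a sum of per-position log-weights dominated by the two HLA-facing
  anchor residues (peptide positions 2 and 9), and converts the score to a
  percent rank against a fixed seeded background of random 9-mers.  This
  reproduces the anchor-residue biology of class I binding with calibrated
  %rank semantics, without any trained model.
* :func:`parse_external_predictions` — an adapter for tabular output from
  external predictors (NetMHC-style columns).

A peptide is called a *strong binder* for an allele when its percent rank is
at or below 0.5 (configurable): it scores within the top 0.5% of random
natural peptides for that allele.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .windows import CANONICAL_AA, EPITOPE_LENGTH

STRONG_RANK_THRESHOLD = 0.5
ANCHOR_POSITIONS = (2, 9)  # 1-based peptide positions facing the HLA groove

_AA_INDEX = {aa: i for i, aa in enumerate(CANONICAL_AA)}

#: columns of a binding-record table
BINDING_COLUMNS = ["peptide", "allele", "affinity", "percent_rank"]


class PredictionError(ValueError):
    pass


@dataclass(frozen=True)
class SyntheticAllele:
    """A synthetic HLA class I allele with an anchor-driven binding motif.

    ``weights`` is a 9x20 array of per-position amino-acid log-weights; rows
    for the anchor positions (2 and 9) carry the dominant weight mass, the
    remaining TCR-facing positions are comparatively flat.
    """

    name: str
    locus: str
    weights: np.ndarray
    frequency: float = 0.0

    def __post_init__(self):
        w = np.asarray(self.weights, dtype=float)
        if w.shape != (EPITOPE_LENGTH, len(CANONICAL_AA)):
            raise ValueError(f"weights must be 9x20, got {w.shape}")


def rank_to_affinity(percent_rank: np.ndarray | float) -> np.ndarray | float:
    """Fixed monotone map from percent rank to a predicted IC50 in nM.

    Anchored so that top-ranked peptides land in the tens of nM and the
    weakest in the tens of thousands, matching the dynamic range binding
    predictors report.  Monotone increasing in rank, so rank order and
    affinity order agree.
    """
    r = np.asarray(percent_rank, dtype=float)
    log_lo, log_hi = np.log(20.0), np.log(50000.0)
    aff = np.exp(log_lo + (log_hi - log_lo) * (r / 100.0) ** 0.3)
    if np.isscalar(percent_rank):
        return float(aff)
    return aff


def encode_peptides(peptides: Sequence[str]) -> np.ndarray:
    """Map 9-mers to an (n, 9) array of amino-acid indices; validates input."""
    n = len(peptides)
    out = np.empty((n, EPITOPE_LENGTH), dtype=np.int64)
    for i, pep in enumerate(peptides):
        if len(pep) != EPITOPE_LENGTH:
            raise PredictionError(f"peptide {pep!r} is not a 9-mer")
        try:
            out[i] = [_AA_INDEX[aa] for aa in pep]
        except KeyError as exc:
            raise PredictionError(f"peptide {pep!r} contains non-canonical {exc}") from exc
    return out


class MotifPredictor:
    """Deterministic anchor-motif binding predictor with calibrated %rank.

    Scores are compared against a precomputed background of
    ``background_size`` pseudo-random 9-mers drawn once from a seeded
    generator, so percent ranks approximate the peptide's quantile among
    random peptides and the whole predictor is reproducible given the allele
    parameterisation.
    """

    def __init__(
        self,
        alleles: Sequence[SyntheticAllele],
        background_size: int = 100_000,
        background_seed: int = 20_200_306,
    ):
        if not alleles:
            raise ValueError("allele panel is empty")
        self.alleles = list(alleles)
        self._by_name = {a.name: a for a in self.alleles}
        if len(self._by_name) != len(self.alleles):
            raise ValueError("duplicate allele names in panel")
        rng = np.random.default_rng(background_seed)
        self._background = rng.integers(
            0, len(CANONICAL_AA), size=(background_size, EPITOPE_LENGTH)
        )
        # sorted background scores per allele, for quantile lookup
        self._bg_sorted = {
            a.name: np.sort(self._score_encoded(self._background, a)) for a in self.alleles
        }

    @property
    def allele_names(self) -> list[str]:
        return [a.name for a in self.alleles]

    @staticmethod
    def _score_encoded(encoded: np.ndarray, allele: SyntheticAllele) -> np.ndarray:
        return allele.weights[np.arange(EPITOPE_LENGTH), encoded].sum(axis=1)

    def score(self, peptides: Sequence[str], allele: str) -> np.ndarray:
        """Raw motif scores (higher = better binder) for one allele."""
        return self._score_encoded(encode_peptides(peptides), self._allele(allele))

    def _allele(self, name: str) -> SyntheticAllele:
        try:
            return self._by_name[name]
        except KeyError:
            raise PredictionError(
                f"unknown allele {name!r}; panel: {', '.join(self.allele_names)}"
            ) from None

    def percent_rank(self, peptides: Sequence[str], allele: str) -> np.ndarray:
        """Percent of background peptides scoring strictly better; in [0, 100]."""
        scores = self.score(peptides, allele)
        bg = self._bg_sorted[allele]
        n_better = bg.size - np.searchsorted(bg, scores, side="right")
        return 100.0 * n_better / bg.size

    def predict(
        self, peptides: Sequence[str], alleles: Sequence[str] | None = None
    ) -> pd.DataFrame:
        """Binding records for every (peptide, allele) pair.

        Returns a DataFrame with columns peptide, allele, affinity (nM),
        percent_rank; exactly ``len(peptides) * len(alleles)`` rows.
        """
        if alleles is None:
            alleles = self.allele_names
        encoded = encode_peptides(peptides)
        frames = []
        for name in alleles:
            allele = self._allele(name)
            scores = self._score_encoded(encoded, allele)
            bg = self._bg_sorted[name]
            ranks = 100.0 * (bg.size - np.searchsorted(bg, scores, side="right")) / bg.size
            frames.append(
                pd.DataFrame(
                    {
                        "peptide": list(peptides),
                        "allele": name,
                        "affinity": rank_to_affinity(ranks),
                        "percent_rank": ranks,
                    }
                )
            )
        return pd.concat(frames, ignore_index=True)[BINDING_COLUMNS]


def is_strong_binder(
    percent_rank: float | np.ndarray, threshold: float = STRONG_RANK_THRESHOLD
):
    """True when percent rank is at or below the strong-binder threshold."""
    return np.asarray(percent_rank) <= threshold if not np.isscalar(percent_rank) else percent_rank <= threshold


def aggregate_ranks(
    ranks: np.ndarray, window_variant: np.ndarray, n_variants: int
) -> np.ndarray:
    """Best (minimum) percent rank per variant from a window-level rank matrix.

    ``ranks`` is (n_windows, n_alleles); ``window_variant`` maps each window
    row to a variant index in ``0..n_variants-1`` and must be sorted so that
    windows of one variant are contiguous.  Returns (n_variants, n_alleles).
    """
    ranks = np.asarray(ranks, dtype=float)
    window_variant = np.asarray(window_variant)
    if np.any(np.diff(window_variant) < 0):
        raise ValueError("window_variant must be sorted")
    counts = np.bincount(window_variant, minlength=n_variants)
    if np.any(counts == 0):
        raise PredictionError("every variant needs at least one window")
    starts = np.concatenate([[0], np.cumsum(counts)[:-1]])
    return np.minimum.reduceat(ranks, starts, axis=0)


def aggregate_variant_allele(
    windows: pd.DataFrame,
    records: pd.DataFrame,
    alleles: Sequence[str] | None = None,
    threshold: float = STRONG_RANK_THRESHOLD,
) -> pd.DataFrame:
    """Per-(variant, allele) summary of the best-binding mutant window.

    ``windows`` is a windows table (variant_id, start, mutant, ...);
    ``records`` a binding-record table covering every mutant peptide for every
    panel allele.  The best window is the one with the lowest percent rank,
    ties broken by lower affinity then lexicographically smaller peptide.

    Returns one row per (variant_id, allele) — cardinality is exactly
    ``n_variants * n_alleles`` — with columns variant_id, allele, best_rank,
    best_affinity, best_start, best_peptide, strong.
    """
    if alleles is None:
        alleles = sorted(records["allele"].unique())
    records = records[records["allele"].isin(alleles)]
    merged = windows[["variant_id", "start", "mutant"]].merge(
        records, left_on="mutant", right_on="peptide", how="left"
    )
    if merged["percent_rank"].isna().any():
        missing = merged.loc[merged["percent_rank"].isna(), "mutant"].unique()
        raise PredictionError(
            f"missing binding records for peptides: {', '.join(missing[:5])}"
        )
    merged = merged.sort_values(
        ["variant_id", "allele", "percent_rank", "affinity", "peptide"],
        kind="mergesort",
    )
    best = merged.drop_duplicates(["variant_id", "allele"], keep="first")
    summaries = best.rename(
        columns={
            "percent_rank": "best_rank",
            "affinity": "best_affinity",
            "start": "best_start",
            "peptide": "best_peptide",
        }
    )[["variant_id", "allele", "best_rank", "best_affinity", "best_start", "best_peptide"]]
    summaries = summaries.reset_index(drop=True)
    n_variants = windows["variant_id"].nunique()
    expected = n_variants * len(alleles)
    if len(summaries) != expected:
        missing = set(alleles) - set(summaries["allele"].unique())
        raise PredictionError(
            f"incomplete grid: {len(summaries)} summaries for {n_variants} variants x "
            f"{len(alleles)} alleles (missing alleles: {sorted(missing)})"
        )
    summaries["strong"] = summaries["best_rank"] <= threshold
    return summaries


def _normalize_allele(raw: str) -> str:
    """Normalise an allele name to LOCUS*GG:PP (strip HLA- prefix, add '*')."""
    name = raw.strip().upper()
    if name.startswith("HLA-"):
        name = name[4:]
    if "*" not in name and name[:1].isalpha():
        # e.g. A02:01 -> A*02:01
        i = 1
        while i < len(name) and name[i].isalpha():
            i += 1
        name = name[:i] + "*" + name[i:]
    return name


def parse_external_predictions(path: str | Path) -> pd.DataFrame:
    """Read binding records from an external predictor's tabular output.

    Expects a TSV with header columns peptide, allele, affinity_nM,
    percent_rank.  Allele names are normalised (``HLA-A02:01`` -> ``A*02:01``);
    malformed rows raise with their line number; duplicate (peptide, allele)
    pairs keep the first occurrence with a warning.
    """
    path = Path(path)
    df = pd.read_csv(path, sep="\t", dtype=str)
    if df.empty:
        warnings.warn(f"{path}: no prediction rows")
        return pd.DataFrame(columns=BINDING_COLUMNS)
    required = ["peptide", "allele", "affinity_nM", "percent_rank"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise PredictionError(f"{path}: missing columns {missing}; expected {required}")
    records = []
    for idx, row in df.iterrows():
        line = idx + 2  # header is line 1
        try:
            affinity = float(row["affinity_nM"])
            rank = float(row["percent_rank"])
        except (TypeError, ValueError):
            raise PredictionError(f"{path}:{line}: non-numeric affinity or rank") from None
        if not 0 <= rank <= 100:
            raise PredictionError(f"{path}:{line}: percent_rank {rank} outside [0, 100]")
        if affinity <= 0:
            raise PredictionError(f"{path}:{line}: affinity {affinity} must be positive")
        peptide = str(row["peptide"]).strip().upper()
        if len(peptide) != EPITOPE_LENGTH:
            raise PredictionError(f"{path}:{line}: peptide {peptide!r} is not a 9-mer")
        records.append((peptide, _normalize_allele(row["allele"]), affinity, rank))
    out = pd.DataFrame(records, columns=BINDING_COLUMNS)
    dups = out.duplicated(["peptide", "allele"])
    if dups.any():
        warnings.warn(f"{path}: {int(dups.sum())} duplicate (peptide, allele) rows; keeping first")
        out = out[~dups].reset_index(drop=True)
    return out
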