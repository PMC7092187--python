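"""Model front door: fit immunoediting statistics to a cohort.

`ImmunoeditingModel` bundles the three inputs every editing analysis needs —
a cohort (genotypes + harbored variants), a presentation map (per-variant
strong-binding allele sets), and population allele frequencies — and `fit()`
runs the allele-, variant-, patient- and histology-level observed:expected
analyses, returning an `ImmunoeditingResults` with tidy tables, composite
scores and a text `summary()`.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .editing import (
    CohortTable,
    allele_editing_table,
    editing_scores,
    histology_editing,
    patient_editing,
    silent_enrichment,
    variant_editing,
)
from .presentation import (
    AlleleFrequencyTable,
    PresentationMap,
    patients_with_silent_fraction,
)


class ImmunoeditingModel:
    """Observed-vs-expected immunoediting model for a tumor cohort.

    Parameters
    ----------
    cohort : CohortTable
        Patient genotypes, histologies and harbored variants.
    presentation : PresentationMap
        Per-variant strong-binding allele sets and carrier probabilities.
    freqs : AlleleFrequencyTable
        Population class I allele frequencies.
    min_allele_freq : float
        Allele-level tests are restricted to alleles above this population
        frequency (default 0.05): the observed:expected comparison is powered
        only for common alleles.
    breadths : mapping, optional
        Per-allele fraction of neoantigens bound strongly (from the summary
        grid); required for composite editing scores.
    """

    def __init__(
        self,
        cohort: CohortTable,
        presentation: PresentationMap,
        freqs: AlleleFrequencyTable,
        min_allele_freq: float = 0.05,
        breadths: Mapping[str, float] | pd.Series | None = None,
        carrier_mode: str = "diploid",
    ):
        self.cohort = cohort
        self.presentation = presentation
        self.freqs = freqs
        self.min_allele_freq = min_allele_freq
        self.breadths = breadths
        self.carrier_mode = carrier_mode

    @classmethod
    def from_tables(
        cls,
        genotype_table,
        variant_table,
        frequency_table,
        summaries: pd.DataFrame,
        **kwargs,
    ) -> "ImmunoeditingModel":
        """Build from file paths plus an aggregated summary grid."""
        from .io import (
            membership_from_occurrences,
            read_frequency_table,
            read_genotype_table,
            read_variant_table,
        )
        from .presentation import breadth_table, call_silent

        variants, occurrences = read_variant_table(variant_table)
        freqs = read_frequency_table(frequency_table)
        pmap = call_silent(summaries, freqs)
        membership = membership_from_occurrences(occurrences, variants)
        cohort = read_genotype_table(genotype_table, membership)
        kwargs.setdefault("breadths", breadth_table(summaries))
        return cls(cohort, pmap, freqs, **kwargs)

    def fit(
        self,
        levels: Sequence[str] = ("allele", "variant", "patient", "histology"),
    ) -> "ImmunoeditingResults":
        """Run the requested analysis levels and collect results."""
        out = ImmunoeditingResults(model=self)
        if "allele" in levels:
            table = allele_editing_table(
                self.cohort, self.presentation, self.freqs,
                min_allele_freq=self.min_allele_freq, mode="carrier",
            )
            out.allele_results = table
            tested = table[table["note"].isna()]
            if self.breadths is not None and not tested.empty:
                out.allele_scores = editing_scores(tested, self.breadths, self.freqs)
        if "variant" in levels:
            vids = self.cohort.membership["variant_id"].unique()
            rows = [
                variant_editing(v, self.cohort, self.presentation, self.freqs,
                                self.carrier_mode).to_dict()
                for v in vids
            ]
            out.variant_results = pd.DataFrame(rows)
        if "patient" in levels:
            rows = [
                patient_editing(p, self.cohort, self.presentation, self.freqs,
                                self.carrier_mode).to_dict()
                for p in self.cohort.patient_ids
            ]
            out.patient_results = pd.DataFrame(rows)
        if "histology" in levels:
            rows = [
                histology_editing(self.cohort, h, self.presentation, self.freqs,
                                  self.carrier_mode).to_dict()
                for h in self.cohort.histologies
            ]
            out.histology_results = pd.DataFrame(rows)
        out.silent = silent_enrichment(self.cohort, self.presentation)
        out.silent_patient_fraction = patients_with_silent_fraction(
            self.cohort, self.presentation
        )
        return out


@dataclass
class ImmunoeditingResults:
    """Fitted immunoediting tables with a text summary.

    Each per-level table carries unit, n, expected, observed, ratio
    (observed:expected; 0 = complete editing, 1 = none), p and BH q.
    """

    model: ImmunoeditingModel
    allele_results: pd.DataFrame | None = None
    allele_scores: pd.DataFrame | None = None
    variant_results: pd.DataFrame | None = None
    patient_results: pd.DataFrame | None = None
    histology_results: pd.DataFrame | None = None
    silent: tuple[float, float, float] | None = None
    silent_patient_fraction: float | None = None

    def significant_alleles(self, alpha: float = 0.05, use_fdr: bool = True) -> list[str]:
        """Alleles significantly underrepresented among binder-harboring patients."""
        if self.allele_results is None:
            raise ValueError("allele level was not fitted")
        t = self.allele_results[self.allele_results["note"].isna()]
        col = "q" if use_fdr else "p"
        return t.loc[t[col] < alpha, "unit"].tolist()

    def summary(self) -> str:
        model = self.model
        lines = [
            "Immunoediting model summary",
            "=" * 60,
            f"patients: {model.cohort.n_patients}    "
            f"variants in map: {len(model.presentation.frame)}    "
            f"histologies: {len(model.cohort.histologies)}",
        ]
        if self.silent is not None:
            obs, base, p = self.silent
            lines.append(
                f"silent variants: {base:.2%} of characterised, "
                f"{obs:.2%} of occurrences (enrichment p = {_fmt_p(p)})"
            )
        if self.silent_patient_fraction is not None:
            lines.append(
                f"patients with >=1 silent variant: {self.silent_patient_fraction:.1%}"
            )
        if self.allele_results is not None:
            tested = self.allele_results[self.allele_results["note"].isna()]
            lines += [
                "",
                f"Allele level ({len(tested)} common alleles tested)",
                "-" * 60,
                tested[["unit", "n", "expected", "observed", "ratio", "p", "q"]]
                .round(4)
                .to_string(index=False),
            ]
        if self.allele_scores is not None and not self.allele_scores.empty:
            top = self.allele_scores.head(5).round(4)
            lines += ["", "Top editing scores (breadth x underrepresentation)",
                      "-" * 60, top.to_string(index=False)]
        if self.histology_results is not None:
            lines += [
                "",
                "Histology level",
                "-" * 60,
                self.histology_results[
                    ["unit", "n", "expected", "observed", "ratio", "p"]
                ].round(4).to_string(index=False),
            ]
        return "\n".join(lines)


def _fmt_p(p: float) -> str:
    if p is None or (isinstance(p, float) and np.isnan(p)):
        return "n/a"
    return f"{p:.3g}"
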