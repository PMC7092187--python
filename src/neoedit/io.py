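"""File formats, run manifest and the end-to-end pipeline.

All tabular I/O is TSV (tab-delimited, header row, UTF-8, '.' decimal).
Coordinates in files are 1-based protein residues.  Allele names are
normalised to ``LOCUS*GG:PP`` at every boundary.

Formats:

* proteins — FASTA; record ids must match the variant table's protein_id.
* variants — columns protein_id, position, ref_aa, alt_aa, patient_id,
  histology; one row per (variant, patient) occurrence.
* genotypes — columns patient_id, A1, A2, B1, B2, C1, C2, histology.
* frequencies — columns allele, locus, frequency.
"""

from __future__ import annotations

import hashlib
import json
import logging
import sys
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
from Bio import SeqIO

from . import __version__
from .binding import (
    MotifPredictor,
    _normalize_allele,
    aggregate_variant_allele,
)
from .editing import (
    LOCUS_COLUMNS,
    CohortTable,
    allele_editing_table,
    editing_scores,
    silent_enrichment,
)
from .presentation import (
    AlleleFrequencyTable,
    PresentationMap,
    breadth_table,
    call_silent,
    compute_profile,
)
from .simulate import SimulationConfig, make_panel, make_proteome, make_variants, simulate_cohort
from .windows import ProteinRecord, VariantRecord, validate_variants, windows_frame

log = logging.getLogger("neoedit")


class InputError(ValueError):
    pass


# ---------------------------------------------------------------------------
# FASTA


def read_fasta(path: str | Path) -> list[ProteinRecord]:
    """Protein records from FASTA; duplicate ids are an error; upper-cased."""
    path = Path(path)
    records = []
    seen = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise InputError(f"{path}: duplicate FASTA id {rec.id!r}")
        seen.add(rec.id)
        seq = str(rec.seq).upper()
        records.append(ProteinRecord(id=rec.id, sequence=seq))
    if not records:
        raise InputError(f"{path}: no FASTA records")
    for rec in records:
        bad = rec.noncanonical_positions
        if bad:
            log.warning("%s: non-canonical letters at positions %s", rec.id, bad[:5])
    return records


def write_fasta(path: str | Path, proteins: list[ProteinRecord]) -> None:
    with open(path, "w") as fh:
        for p in proteins:
            fh.write(f">{p.id}\n")
            for i in range(0, len(p.sequence), 60):
                fh.write(p.sequence[i : i + 60] + "\n")


# ---------------------------------------------------------------------------
# tables


def _read_tsv(path: str | Path, required: list[str]) -> pd.DataFrame:
    path = Path(path)
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise InputError(f"{path}: missing columns {missing}; expected header {required}")
    return df


def read_variant_table(path: str | Path) -> tuple[list[VariantRecord], pd.DataFrame]:
    """Variant occurrences -> unique VariantRecords plus the raw occurrence table.

    One input row per (variant, patient) occurrence; rows are aggregated to
    unique (protein_id, position, ref_aa, alt_aa) records internally.
    """
    required = ["protein_id", "position", "ref_aa", "alt_aa", "patient_id", "histology"]
    df = _read_tsv(path, required)
    bad = df["position"].isna() | (pd.to_numeric(df["position"], errors="coerce").isna())
    if bad.any():
        line = int(df.index[bad][0]) + 2
        raise InputError(f"{path}:{line}: non-numeric position")
    df["position"] = df["position"].astype(int)
    variants = []
    for key, grp in df.groupby(["protein_id", "position", "ref_aa", "alt_aa"], sort=True):
        occurrences = tuple(zip(grp["patient_id"].astype(str), grp["histology"].astype(str)))
        variants.append(
            VariantRecord(
                gene=str(key[0]), position=int(key[1]), ref_aa=str(key[2]),
                alt_aa=str(key[3]), occurrences=occurrences,
            )
        )
    return variants, df


def write_variant_table(path: str | Path, variants: list[VariantRecord]) -> None:
    rows = []
    for v in variants:
        occurrences = v.occurrences or ((".", "."),)
        for patient, hist in occurrences:
            rows.append((v.gene, v.position, v.ref_aa, v.alt_aa, patient, hist))
    pd.DataFrame(
        rows, columns=["protein_id", "position", "ref_aa", "alt_aa", "patient_id", "histology"]
    ).to_csv(path, sep="\t", index=False)


def read_frequency_table(path: str | Path) -> AlleleFrequencyTable:
    return AlleleFrequencyTable(_read_tsv(path, ["allele", "locus", "frequency"]))


def read_genotype_table(path: str | Path, membership: pd.DataFrame | None = None) -> CohortTable:
    """Genotype TSV -> CohortTable; ``membership`` supplies harbored variants."""
    required = ["patient_id", *LOCUS_COLUMNS, "histology"]
    df = _read_tsv(path, required)
    for c in LOCUS_COLUMNS:
        if df[c].isna().any():
            line = int(df.index[df[c].isna()][0]) + 2
            raise InputError(f"{path}:{line}: missing allele in column {c}")
        df[c] = df[c].astype(str).map(_normalize_allele)
    if membership is None:
        membership = pd.DataFrame(columns=["patient_id", "variant_id"])
    return CohortTable(patients=df, membership=membership)


def write_genotype_table(path: str | Path, cohort: CohortTable) -> None:
    cols = ["patient_id", *LOCUS_COLUMNS, "histology"]
    cohort.patients[cols].to_csv(path, sep="\t", index=False)


def membership_from_occurrences(
    occurrences: pd.DataFrame, variants: list[VariantRecord]
) -> pd.DataFrame:
    """Occurrence rows -> (patient_id, variant_id) membership table."""
    key_to_id = {
        (v.gene, v.position, v.ref_aa, v.alt_aa): v.variant_id for v in variants
    }
    vids = [
        key_to_id[(r.protein_id, int(r.position), r.ref_aa, r.alt_aa)]
        for r in occurrences.itertuples()
    ]
    return pd.DataFrame(
        {"patient_id": occurrences["patient_id"].astype(str).to_numpy(), "variant_id": vids}
    )


def cohort_to_variant_table(
    path: str | Path, cohort: CohortTable, variants: list[VariantRecord]
) -> None:
    """Write a cohort's membership as a variant occurrence table."""
    by_id = {v.variant_id: v for v in variants}
    hist = dict(zip(cohort.patients["patient_id"], cohort.patients["histology"]))
    rows = []
    for r in cohort.membership.itertuples():
        v = by_id[r.variant_id]
        rows.append((v.gene, v.position, v.ref_aa, v.alt_aa, r.patient_id, hist[r.patient_id]))
    pd.DataFrame(
        rows, columns=["protein_id", "position", "ref_aa", "alt_aa", "patient_id", "histology"]
    ).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# manifest and pipeline


@dataclass
class RunManifest:
    """Provenance record written at the end of a pipeline run."""

    seed: int
    version: str = __version__
    inputs: dict = field(default_factory=dict)  # path -> sha256
    config: dict = field(default_factory=dict)
    row_counts: dict = field(default_factory=dict)

    def add_input(self, path: str | Path) -> None:
        digest = hashlib.sha256(Path(path).read_bytes()).hexdigest()
        self.inputs[str(path)] = digest

    def write(self, path: str | Path) -> None:
        payload = {
            "version": self.version,
            "seed": self.seed,
            "inputs": self.inputs,
            "config": self.config,
            "row_counts": self.row_counts,
        }
        tmp = Path(str(path) + ".partial")
        tmp.write_text(json.dumps(payload, indent=2, sort_keys=True))
        tmp.replace(path)


def run_pipeline(
    protein_fasta: str | Path,
    variant_table: str | Path,
    frequency_table: str | Path,
    genotype_table: str | Path,
    outdir: str | Path,
    seed: int = 0,
    strong_rank_threshold: float = 0.5,
    min_allele_freq: float = 0.05,
    predictor: MotifPredictor | None = None,
    panel_config: SimulationConfig | None = None,
) -> Path:
    """Run every stage (windows -> predict -> aggregate -> map -> editing).

    When no external ``predictor`` is supplied, a synthetic motif predictor
    parameterised from ``panel_config`` (or a default config at ``seed``) is
    built; its allele panel must cover the frequency table.  Stage outputs are
    written as TSVs under ``outdir`` together with a run manifest.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest = RunManifest(seed=seed)
    for p in (protein_fasta, variant_table, frequency_table, genotype_table):
        if not Path(p).exists():
            raise InputError(f"missing input: {p}")
        manifest.add_input(p)

    log.info("reading inputs")
    proteins = read_fasta(protein_fasta)
    variants, occurrences = read_variant_table(variant_table)
    freqs = read_frequency_table(frequency_table)
    valid, rejected = validate_variants(proteins, variants)
    rejected.to_csv(outdir / "rejected_variants.tsv", sep="\t", index=False)

    log.info("stage windows: %d valid variants", len(valid))
    windows = windows_frame(proteins, valid)
    windows.to_csv(outdir / "windows.tsv", sep="\t", index=False)

    if predictor is None:
        cfg = panel_config or SimulationConfig(seed=seed)
        alleles, panel_freqs = make_panel(cfg)
        predictor = MotifPredictor(alleles, background_size=cfg.background_size)
    panel = [a for a in predictor.allele_names if a in freqs]
    if not panel:
        raise InputError("predictor panel shares no alleles with the frequency table")

    log.info("stage predict: %d peptides x %d alleles", windows["mutant"].nunique(), len(panel))
    records = predictor.predict(sorted(windows["mutant"].unique()), panel)
    records.to_csv(outdir / "binding.tsv", sep="\t", index=False)

    log.info("stage aggregate")
    summaries = aggregate_variant_allele(windows, records, panel, strong_rank_threshold)
    summaries.to_csv(outdir / "summaries.tsv", sep="\t", index=False)

    log.info("stage map")
    pmap = call_silent(summaries, freqs, panel)
    pmap.to_frame().to_csv(outdir / "presentation_map.tsv", sep="\t", index=False)

    log.info("stage profiles")
    profiles = []
    for protein in proteins:
        prof = compute_profile(protein, predictor, freqs, strong_rank_threshold, panel)
        f = prof.frame.copy()
        f.insert(0, "protein", protein.id)
        profiles.append(f)
    pd.concat(profiles, ignore_index=True).to_csv(outdir / "profiles.tsv", sep="\t", index=False)

    log.info("stage editing")
    membership = membership_from_occurrences(occurrences, variants)
    membership = membership[membership["variant_id"].isin(pmap.binding_sets)]
    cohort = read_genotype_table(genotype_table, membership)
    allele_results = allele_editing_table(cohort, pmap, freqs, min_allele_freq=min_allele_freq)
    allele_results.to_csv(outdir / "allele_editing.tsv", sep="\t", index=False)
    tested = allele_results[allele_results["note"].isna()]
    if not tested.empty:
        scores = editing_scores(tested, breadth_table(summaries), freqs)
        scores.to_csv(outdir / "editing_scores.tsv", sep="\t", index=False)
    obs, base, p = silent_enrichment(cohort, pmap)
    pd.DataFrame(
        [{"observed_fraction": obs, "baseline_fraction": base, "p": p}]
    ).to_csv(outdir / "silent_enrichment.tsv", sep="\t", index=False)

    manifest.config = {
        "strong_rank_threshold": strong_rank_threshold,
        "min_allele_freq": min_allele_freq,
        "panel": panel,
    }
    manifest.row_counts = {
        "proteins": len(proteins),
        "variants": len(valid),
        "rejected": len(rejected),
        "windows": len(windows),
        "binding_records": len(records),
        "summaries": len(summaries),
        "patients": cohort.n_patients,
    }
    manifest.write(outdir / "manifest.json")
    log.info("pipeline complete: %s", outdir)
    return outdir


def simulate_to_files(config: SimulationConfig, outdir: str | Path) -> Path:
    """Emit a full synthetic study (FASTA + TSVs) the pipeline can consume."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rng = config.rng()
    alleles, freqs = make_panel(config, rng)
    predictor = MotifPredictor(alleles, background_size=config.background_size)
    proteome = make_proteome(config, rng)
    variants = make_variants(proteome, config.n_variants, rng)
    windows = windows_frame(proteome, variants)
    records = predictor.predict(sorted(windows["mutant"].unique()), predictor.allele_names)
    summaries = aggregate_variant_allele(
        windows, records, predictor.allele_names, config.strong_rank_threshold
    )
    pmap = call_silent(summaries, freqs, predictor.allele_names)
    cohort = simulate_cohort(config, freqs, variants, pmap, rng)

    write_fasta(outdir / "proteins.fasta", proteome)
    freqs.to_tsv(outdir / "frequencies.tsv")
    write_genotype_table(outdir / "genotypes.tsv", cohort)
    cohort_to_variant_table(outdir / "variants.tsv", cohort, variants)
    return outdir


def setup_logging(verbose: bool = False, quiet: bool = False) -> None:
    level = logging.WARNING if quiet else (logging.DEBUG if verbose else logging.INFO)
    logging.basicConfig(
        stream=sys.stderr, level=level, format="%(asctime)s %(name)s %(levelname)s %(message)s"
    )
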