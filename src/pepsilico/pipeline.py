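"""End-to-end orchestration: screening -> motif profiling -> digestion ->
descriptors -> physicochemical/toxicity -> drug-likeness.

``run_pipeline`` executes the whole chain deterministically for a given
config and input, writes one CSV per stage plus a combined JSON report, and
returns the in-memory :class:`RunReport`.  Peptides occurring in several
samples are processed once per sample and cross-referenced by their
sequence, which serves as the shared peptide id.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import pandas as pd

from . import admet as _admet
from .chem import build_peptide_graph
from .descriptors import DescriptorSet, describe, descriptor_report
from .digestion import (
    DigestResult,
    digest,
    digest_report,
    load_enzyme_rules,
    released_active_fragments,
)
from .motifs import ACTIVITIES, ActivityProfile, load_motif_db, profile_report, scan_motifs
from .peptide import AminoAcidTable, DEFAULT_PKA_SET, DEFAULT_HYDROPHOBICITY_SCALE
from .physchem import DEFAULT_PREDICTOR, physchem_report
from .screening import RankedPeptide, read_fasta, read_scored_csv, screen_by_score
from .synthetic import GeneratorSpec, generate_peptides


class PipelineError(RuntimeError):
    pass


@dataclass(frozen=True)
class RunConfig:
    input_path: str | None = None
    input_format: str = "csv"  # csv | fasta | synthetic
    threshold: float = 0.9
    activities: tuple[str, ...] = ACTIVITIES
    enzyme_rule_set: str = "gi-default"
    pka_set: str = DEFAULT_PKA_SET
    hydrophobicity_scale: str = DEFAULT_HYDROPHOBICITY_SCALE
    predictor: str = DEFAULT_PREDICTOR
    output_dir: str | None = None
    seed: int = 0  # used only when input_format == "synthetic"
    n_synthetic: int = 100

    def __post_init__(self) -> None:
        if not 0.0 <= self.threshold <= 1.0:
            raise PipelineError(f"threshold {self.threshold} outside [0, 1]")
        unknown = set(self.activities) - set(ACTIVITIES)
        if unknown:
            raise PipelineError(f"unknown activities: {sorted(unknown)}")

    def hash(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


@dataclass
class PeptideRecord:
    """All stage outputs for one screened peptide in one sample."""

    peptide: str
    sample: str
    score: float
    profiles: dict[str, ActivityProfile]
    digest: DigestResult
    descriptors: dict[str, DescriptorSet]
    released: dict[str, list[tuple[str, tuple[int, int]]]]


@dataclass
class RunReport:
    config: RunConfig
    records: list[PeptideRecord]
    physchem: pd.DataFrame
    admet: pd.DataFrame
    summary: dict
    provenance: dict = field(default_factory=dict)


def _load_input(config: RunConfig) -> list[RankedPeptide]:
    if config.input_format == "synthetic":
        return generate_peptides(
            GeneratorSpec(n_peptides=config.n_synthetic, seed=config.seed)
        )
    if config.input_path is None:
        raise PipelineError("input_path is required for csv/fasta input")
    path = Path(config.input_path)
    if not path.exists():
        raise PipelineError(f"input file not found: {path}")
    if config.input_format == "csv":
        return read_scored_csv(path)
    if config.input_format == "fasta":
        return read_fasta(path)
    raise PipelineError(f"unknown input format {config.input_format!r}")


def run_pipeline(config: RunConfig) -> RunReport:
    """Execute all stages; write per-stage reports when output_dir is set."""
    items = _load_input(config)
    db = load_motif_db()
    rules = load_enzyme_rules(config.enzyme_rule_set)
    table = AminoAcidTable.default()

    screened = screen_by_score(items, config.threshold)
    records: list[PeptideRecord] = []
    for item in screened:
        profiles = {
            act: scan_motifs(item.peptide, db, act) for act in config.activities
        }
        result = digest(item.peptide, rules)
        descriptors = {
            act: describe(result, profiles[act], db) for act in config.activities
        }
        released = {
            act: released_active_fragments(result, db, act)
            for act in config.activities
        }
        records.append(
            PeptideRecord(
                peptide=str(item.peptide),
                sample=item.sample_label,
                score=item.score,
                profiles=profiles,
                digest=result,
                descriptors=descriptors,
                released=released,
            )
        )

    # Unique released active fragments, in first-appearance order.
    released_unique: list[str] = []
    for rec in records:
        for act in config.activities:
            for seq, _span in rec.released[act]:
                if seq not in released_unique:
                    released_unique.append(seq)

    from .peptide import parse_peptide

    released_peptides = [parse_peptide(seq) for seq in released_unique]
    physchem = physchem_report(
        released_peptides,
        predictor=config.predictor,
        pka_set=config.pka_set,
        hydrophobicity_scale=config.hydrophobicity_scale,
        table=table,
    )
    admet_profiles = [
        _admet.adme_profile(build_peptide_graph(p)) for p in released_peptides
    ]
    admet = _admet.adme_report(admet_profiles)

    summary = summarize_records(records, config.activities, len(items))
    report = RunReport(
        config=config,
        records=records,
        physchem=physchem,
        admet=admet,
        summary=summary,
        provenance={
            "config_hash": config.hash(),
            "amino_acid_table_version": table.version,
            "motif_db_size": len(db),
            "enzyme_rule_set": config.enzyme_rule_set,
        },
    )
    if config.output_dir is not None:
        _write_reports(report, Path(config.output_dir))
    return report


def summarize_records(
    records: list[PeptideRecord], activities: tuple[str, ...], n_input: int
) -> dict:
    """Per-stage and per-activity counts for a finished run."""
    summary: dict = {
        "n_input": n_input,
        "n_screened": len(records),
        "n_digestion_resistant": sum(1 for r in records if r.digest.resistant),
    }
    for act in activities:
        released = [seq for r in records for seq, _ in r.released[act]]
        summary[f"n_profiled[{act}]"] = sum(
            1 for r in records if r.profiles[act].a > 0
        )
        summary[f"n_released[{act}]"] = len(released)
        summary[f"released_set[{act}]"] = sorted(set(released))
    anti = "antioxidative"
    if anti in activities:
        summary["no_antioxidative_release"] = summary[f"n_released[{anti}]"] == 0
    return summary


def summarize(report: RunReport) -> pd.DataFrame:
    """Summary counts as a two-column table."""
    return pd.DataFrame(
        [(k, json.dumps(v) if isinstance(v, list) else v) for k, v in report.summary.items()],
        columns=["quantity", "value"],
    )


def _write_reports(report: RunReport, out_dir: Path) -> None:
    out_dir.mkdir(parents=True, exist_ok=True)
    cfg = report.config
    screened = pd.DataFrame(
        [
            {"peptide": r.peptide, "sample": r.sample, "score": r.score}
            for r in report.records
        ]
    )
    screened.to_csv(out_dir / "screened.csv", index=False)
    all_profiles = [
        r.profiles[act] for r in report.records for act in cfg.activities
    ]
    profile_report(all_profiles).to_csv(out_dir / "motif_profiles.csv", index=False)
    db = load_motif_db()
    digest_report(
        [r.digest for r in report.records], db, list(cfg.activities)
    ).to_csv(out_dir / "digestion.csv", index=False)
    descriptor_report(
        [r.descriptors[act] for r in report.records for act in cfg.activities]
    ).to_csv(out_dir / "descriptors.csv", index=False)
    report.physchem.to_csv(out_dir / "physchem.csv", index=False)
    report.admet.to_csv(out_dir / "admet.csv", index=False)
    combined = {
        "provenance": report.provenance,
        "summary": report.summary,
        "physchem": report.physchem.to_dict("records"),
        "admet": report.admet.to_dict("records"),
        "peptides": [
            {
                "peptide": r.peptide,
                "sample": r.sample,
                "score": r.score,
                "fragmentation": "_"
                if r.digest.resistant
                else "-".join(r.digest.fragment_sequences),
                "descriptors": {
                    act: {
                        "dht_percent": ds.dht,
                        "ae": ds.ae,
                        "w": ds.w,
                        "w_undefined": ds.w_undefined,
                    }
                    for act, ds in r.descriptors.items()
                },
                "released": {
                    act: [
                        {"fragment": seq, "start": a, "end": b}
                        for seq, (a, b) in frags
                    ]
                    for act, frags in r.released.items()
                },
            }
            for r in report.records
        ],
    }
    (out_dir / "report.json").write_text(json.dumps(combined, indent=2))
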