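"""End-to-end orchestration: QC -> annotate -> spectrum -> null -> call ->
characterize, from one config, with a run manifest for provenance.

Every stage is also callable on its own through the library API; the
pipeline only wires them together and writes their outputs.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import yaml

from . import __version__
from .aa_distance import deltau_recurrence_profile, load_delta_u, placeholder_delta_u
from .burden import burden_frame, burden_table
from .caller import call_cdns, cdns_to_frame, GeneSelectionRecord, summarize_cdn_genes
from .coding import annotate_mutations, count_sites, load_cds_model
from .io import QCConfig, apply_qc_filters, consolidate_patients, read_mutation_table
from .neutral import compute_istar, estimate_rates, excess_table, expected_counts
from .spectrum import spectrum_to_frame, tally_spectrum

import pandas as pd


class PipelineError(RuntimeError):
    """A stage failure, carrying the stage name."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage


@dataclass
class PipelineConfig:
    input_path: str
    cds_fasta: str
    cds_anchors: str
    out_dir: str
    dialect: str = "simple_tsv"
    cancer_type: str = ""
    n_patients: int | None = None  # default: distinct patients after QC
    qc: QCConfig = field(default_factory=QCConfig)
    istar: int | str = "auto"
    selection_table: str | None = None  # TSV gene, w, q_value
    delta_u_table: str | None = None  # TSV aa1, aa2, delta_u; placeholder if absent
    min_group: int = 10
    seed: int = 0

    def __post_init__(self) -> None:
        if self.istar != "auto" and int(self.istar) < 1:
            raise ValueError("istar override must be >= 1")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text())
        if "qc" in raw:
            raw["qc"] = QCConfig(**raw["qc"])
        return cls(**raw)


def run_pipeline(cfg: PipelineConfig) -> dict:
    """Run the full analysis; returns the manifest dict.

    Outputs under ``cfg.out_dir``: filtered.tsv, qc_report.json,
    spectrum.tsv, neutral_fit.json, excess.tsv, cdns.tsv, gene_summary.tsv,
    aa_profile.tsv, burden.tsv, manifest.json.  Deterministic for fixed
    inputs; any stage error raises :class:`PipelineError` naming the stage
    (partial outputs are retained).
    """
    for p in (cfg.input_path, cfg.cds_fasta, cfg.cds_anchors):
        if not Path(p).exists():
            raise PipelineError("config", FileNotFoundError(p))
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "version": __version__,
        "config_hash": hashlib.sha256(
            json.dumps(asdict(cfg), sort_keys=True, default=str).encode()
        ).hexdigest()[:16],
        "stages": {},
    }

    def stage(name):
        def deco(fn):
            try:
                return fn()
            except PipelineError:
                raise
            except Exception as exc:  # noqa: BLE001 - reported with stage name
                raise PipelineError(name, exc) from exc

        return deco

    table = stage("read")(lambda: read_mutation_table(cfg.input_path, cfg.dialect))
    manifest["stages"]["read"] = {"records": len(table), "non_snv_dropped": table.attrs.get("n_non_snv", 0)}

    def _qc():
        filtered, report = apply_qc_filters(table, cfg.qc)
        report.to_json(out / "qc_report.json")
        return filtered, report

    filtered, report = stage("qc")(_qc)
    manifest["stages"]["qc"] = {"records": len(filtered), "removed": report.records_removed_per_rule}

    consolidated = stage("consolidate")(lambda: consolidate_patients(filtered))
    manifest["stages"]["consolidate"] = {"records": len(consolidated)}
    consolidated.to_csv(out / "filtered.tsv", sep="\t", index=False)

    model = stage("cds_model")(lambda: load_cds_model(cfg.cds_fasta, cfg.cds_anchors))
    annotated = stage("annotate")(lambda: annotate_mutations(consolidated, model))
    manifest["stages"]["annotate"] = {
        "records": len(annotated),
        "noncoding_dropped": annotated.attrs.get("n_noncoding", 0),
    }

    def _spectrum():
        counts = count_sites(model)
        n = cfg.n_patients or (annotated["patient_id"].nunique() if len(annotated) else 0)
        return tally_spectrum(annotated, counts, int(n), cfg.cancer_type)

    spec = stage("spectrum")(_spectrum)
    spectrum_to_frame(spec).to_csv(out / "spectrum.tsv", sep="\t", index=False)
    manifest["stages"]["spectrum"] = {"n": spec.n, "L_A": spec.L_A, "L_S": spec.L_S}

    def _null():
        fit = estimate_rates(spec)
        i_max = max([4, *spec.A.keys()])
        exp = expected_counts(spec.L_A, fit.q, i_max)
        observed = {i: spec.A.get(i, 0) for i in range(1, i_max + 1)}
        excess_table(observed, exp).to_csv(out / "excess.tsv", sep="\t", index=False)
        istar = int(cfg.istar) if cfg.istar != "auto" else (
            compute_istar(spec.L_A, fit.q) if fit.q > 0 else 1
        )
        (out / "neutral_fit.json").write_text(
            json.dumps({**asdict(fit), "istar": istar}, indent=2) + "\n"
        )
        return fit, istar

    fit, istar = stage("null")(_null)
    manifest["stages"]["null"] = {"q": fit.q, "nEu_total": fit.nEu_total, "istar": istar}

    def _call():
        cdns = call_cdns(spec, istar)
        du = load_delta_u(cfg.delta_u_table) if cfg.delta_u_table else placeholder_delta_u()
        from dataclasses import replace
        from .aa_distance import delta_u as _du

        cdns = [replace(c, delta_u=_du((c.aa_ref, c.aa_alt), du)) for c in cdns]
        frame = cdns_to_frame(cdns)
        frame["delta_u_provenance"] = du.provenance
        frame.to_csv(out / "cdns.tsv", sep="\t", index=False)
        return cdns, du

    cdns, du = stage("call")(_call)
    manifest["stages"]["call"] = {"cdns": len(cdns), "delta_u_provenance": du.provenance}

    def _genes():
        selection = []
        if cfg.selection_table:
            sel = pd.read_csv(cfg.selection_table, sep="\t")
            selection = [
                GeneSelectionRecord(str(r.gene), float(r.w), float(r.q_value))
                for r in sel.itertuples(index=False)
            ]
        summaries, agg = summarize_cdn_genes(cdns, annotated, selection)
        pd.DataFrame([asdict(s) for s in summaries]).to_csv(
            out / "gene_summary.tsv", sep="\t", index=False
        )
        return agg

    agg = stage("genes")(_genes)
    manifest["stages"]["genes"] = {"cdn_genes": agg.n_cdn_genes, "type_i": agg.n_type_i, "type_ii": agg.n_type_ii}

    def _aa():
        profile = deltau_recurrence_profile(cdns, du, cfg.min_group)
        pd.DataFrame([asdict(p) for p in profile]).to_csv(
            out / "aa_profile.tsv", sep="\t", index=False
        )
        return profile

    profile = stage("aa")(_aa)
    manifest["stages"]["aa"] = {"groups": len(profile)}

    def _burden():
        cdn_level, gene_level = burden_table(annotated, cdns, spec.n)
        burden_frame(cdn_level, gene_level).to_csv(out / "burden.tsv", sep="\t", index=False)
        return cdn_level

    cdn_level = stage("burden")(_burden)
    manifest["stages"]["burden"] = {"mean_cdn_burden": cdn_level.mean}

    (out / "manifest.json").write_text(json.dumps(manifest, indent=2) + "\n")
    return manifest
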