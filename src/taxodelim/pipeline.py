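"""End-to-end orchestration of the polyphasic delineation workflow.

Stages: ITS extraction/dissection -> helix folding -> 16S identities ->
genome/proteome metrics (ANI, AAI, POCP) -> single-copy ortholog tree ->
HGT screen -> threshold delineation. Every stage's outputs land under one
run directory with a manifest (stage -> inputs, outputs, status) and a log;
the run is deterministic given (config, inputs). A stage failure is
recorded and its dependents are skipped.
"""

from __future__ import annotations

import json
import traceback
from dataclasses import dataclass, field
from pathlib import Path

from . import __version__
from .align import HitRecord, global_align, percent_identity
from .config import PipelineConfig
from .decision import CONFLICT, EvidenceBundle, delineate
from .errors import TaxodelimError, UndefinedMetricError
from .fold import element_report, fold, to_dotbracket
from .hgt import calls_to_tsv, screen, summarize
from .its import dissect, extract_its, length_table, load_motifs, regions_to_bed
from .metrics import genome_stats, metric_matrix, pocp_table
from .phylo import align_and_concatenate, bootstrap, single_copy_clusters, to_newick
from .records import SeqRecord


@dataclass
class PipelineInputs:
    focal: str
    genomes: dict[str, SeqRecord] = field(default_factory=dict)
    s16: dict[str, SeqRecord] = field(default_factory=dict)
    proteomes: dict[str, list[SeqRecord]] = field(default_factory=dict)
    hgt_proteome: list[SeqRecord] = field(default_factory=list)
    hgt_hits: list[HitRecord] = field(default_factory=list)
    self_family: str = ""
    outgroup: str | None = None


@dataclass
class PipelineResult:
    run_dir: Path
    manifest: dict
    verdict: dict | None

    @property
    def failed(self) -> bool:
        return any(s["status"] == "failed" for s in self.manifest["stages"].values())

    @property
    def conflicted(self) -> bool:
        return bool(self.verdict) and self.verdict.get("combined") == CONFLICT


def _write(path: Path, text: str) -> None:
    path.write_text(text)


def run_pipeline(config: PipelineConfig, inputs: PipelineInputs, run_dir: str | Path) -> PipelineResult:
    run_dir = Path(run_dir)
    run_dir.mkdir(parents=True, exist_ok=True)
    log_lines: list[str] = [
        f"taxodelim {__version__}",
        f"config_hash {config.config_hash()}",
        f"seed {config.seed}",
    ]
    manifest: dict = {
        "version": __version__,
        "config_hash": config.config_hash(),
        "seed": config.seed,
        "stages": {},
    }
    motifs = load_motifs(config.motif_file)
    state: dict = {}

    def stage(name: str, requires: tuple[str, ...], available: bool, fn):
        entry = {"status": "skipped", "outputs": [], "requires": list(requires)}
        manifest["stages"][name] = entry
        if not available:
            log_lines.append(f"stage {name}: skipped (inputs missing)")
            return
        for dep in requires:
            if manifest["stages"].get(dep, {}).get("status") != "ok":
                log_lines.append(f"stage {name}: skipped (dependency {dep} not ok)")
                return
        try:
            outputs = fn()
            entry["status"] = "ok"
            entry["outputs"] = sorted(str(o.relative_to(run_dir)) for o in outputs)
            log_lines.append(f"stage {name}: ok")
        except TaxodelimError as exc:
            entry["status"] = "failed"
            entry["error"] = str(exc)
            log_lines.append(f"stage {name}: failed ({exc})")
        except Exception as exc:  # pragma: no cover - defensive
            entry["status"] = "failed"
            entry["error"] = f"{type(exc).__name__}: {exc}"
            log_lines.append(f"stage {name}: failed ({exc})")
            log_lines.append(traceback.format_exc())

    def do_its():
        state["its_residues"] = {}
        outputs = []
        dissections = []
        for strain in sorted(inputs.genomes):
            for its in extract_its(inputs.genomes[strain]):
                d = dissect(its, motifs=motifs)
                dissections.append(d)
                state["its_residues"][d.source_id] = its.residues
                bed = run_dir / f"its_regions_{d.source_id}.bed"
                _write(bed, regions_to_bed(d))
                outputs.append(bed)
        state["dissections"] = dissections
        if dissections:
            table = run_dir / "its_length_table.tsv"
            length_table(dissections).to_csv(table, sep="\t")
            outputs.append(table)
        return outputs

    def do_fold():
        lines = ["source\tregion\tsequence\tdotbracket"]
        for d in state["dissections"]:
            for name in ("D1-D1'", "V2", "boxB", "V3"):
                region = d.region(name)
                if region is None or region.length < 5:
                    continue
                seq = state["its_residues"][d.source_id][region.start : region.end]
                s = fold(seq, config.fold)
                lines.append(f"{d.source_id}\t{name}\t{seq}\t{to_dotbracket(s)}")
        out = run_dir / "helix_structures.tsv"
        _write(out, "\n".join(lines) + "\n")
        return [out]

    def do_16s():
        focal = inputs.s16[inputs.focal]
        lines = ["strain\tidentity_16s"]
        idents = {}
        for strain in sorted(inputs.s16):
            if strain == inputs.focal:
                continue
            aln = global_align(focal, inputs.s16[strain])
            idents[strain] = percent_identity(aln)
            lines.append(f"{strain}\t{idents[strain]:.2f}")
        state["s16_identity"] = idents
        out = run_dir / "identity_16s.tsv"
        _write(out, "\n".join(lines) + "\n")
        return [out]

    def do_metrics():
        table, detail = metric_matrix(inputs.genomes, inputs.proteomes, config.ani, config.aai)
        out1 = run_dir / "ani_aai_matrix.tsv"
        table.round(2).to_csv(out1, sep="\t", na_rep="NA")
        ptab = pocp_table(inputs.proteomes, inputs.focal, config.pocp)
        out2 = run_dir / "pocp_table.tsv"
        ptab.round(1).to_csv(out2, sep="\t")
        stats_lines = ["strain\tlength_bp\tgc_percent"]
        for strain in sorted(inputs.genomes):
            length, gc = genome_stats(inputs.genomes[strain])
            stats_lines.append(f"{strain}\t{length}\t{gc:.1f}")
        out3 = run_dir / "genome_stats.tsv"
        _write(out3, "\n".join(stats_lines) + "\n")
        out4 = run_dir / "metric_detail.json"
        _write(out4, json.dumps(detail, indent=1, sort_keys=True))
        state["metric_table"] = table
        state["pocp_table"] = ptab
        return [out1, out2, out3, out4]

    def do_tree():
        clusters = single_copy_clusters(inputs.proteomes, config.aai)
        if not clusters:
            raise UndefinedMetricError("no universal single-copy clusters found")
        sm = align_and_concatenate(clusters, inputs.proteomes)
        result = bootstrap(
            sm,
            n_reps=config.bootstrap_reps,
            seed=config.seed,
            model=config.distance_model,
            outgroup=inputs.outgroup,
        )
        out1 = run_dir / "supermatrix.phy"
        _write(out1, sm.to_phylip())
        out2 = run_dir / "partitions.tsv"
        _write(out2, sm.partition_tsv())
        out3 = run_dir / "tree.nwk"
        _write(out3, "# distance (NJ) stand-in for ML inference; supports = classical bootstrap %\n" + to_newick(result.tree))
        state["n_clusters"] = len(clusters)
        return [out1, out2, out3]

    def do_hgt():
        calls = screen(
            inputs.hgt_proteome,
            inputs.hgt_hits,
            self_family=inputs.self_family,
            self_strain=inputs.focal,
            params=config.hgt,
        )
        summary = summarize(calls)
        out1 = run_dir / "hgt_calls.tsv"
        _write(out1, calls_to_tsv(calls))
        out2 = run_dir / "hgt_summary.json"
        _write(
            out2,
            json.dumps(
                {
                    "n_proteins": summary.n_proteins,
                    "n_candidates": summary.n_candidates,
                    "n_insufficient": summary.n_insufficient,
                    "fraction_candidates": round(summary.fraction_candidates, 4),
                    "donor_families": summary.donor_families,
                    "candidate_ids": summary.candidate_ids,
                },
                indent=1,
                sort_keys=True,
            ),
        )
        return [out1, out2]

    def do_delineate():
        idents = state.get("s16_identity", {})
        table = state.get("metric_table")
        ptab = state.get("pocp_table")
        neighbors = sorted(s for s in inputs.genomes if s != inputs.focal)
        per_neighbor = {}
        for nb in neighbors:
            lo, hi = sorted((nb, inputs.focal))
            bundle = EvidenceBundle(
                s16_identity=idents.get(nb),
                ani=None if table is None else _cell(table, hi, lo),
                aai=None if table is None else _cell(table, lo, hi),
                pocp=None if ptab is None or nb not in ptab.index else float(ptab.loc[nb].iloc[0]),
            )
            v = delineate(bundle, config.thresholds)
            per_neighbor[nb] = {
                "evidence": {
                    "16S": bundle.s16_identity,
                    "ANI": bundle.ani,
                    "AAI": bundle.aai,
                    "POCP": bundle.pocp,
                },
                "per_evidence": v.per_evidence,
                "combined": v.combined,
                "conflicts": list(v.conflicts),
                "rationale": list(v.rationale),
            }
        nearest = max(idents, key=idents.get) if idents else (neighbors[0] if neighbors else None)
        verdict = {
            "focal": inputs.focal,
            "nearest_neighbor": nearest,
            "combined": per_neighbor[nearest]["combined"] if nearest else "unavailable",
            "per_neighbor": per_neighbor,
        }
        out = run_dir / "verdict.json"
        _write(out, json.dumps(verdict, indent=1, sort_keys=True))
        state["verdict"] = verdict
        return [out]

    stage("extract_dissect", (), bool(inputs.genomes), do_its)
    stage("fold_helices", ("extract_dissect",), bool(inputs.genomes), do_fold)
    stage("identity_16s", (), inputs.focal in inputs.s16 and len(inputs.s16) > 1, do_16s)
    stage(
        "genome_metrics",
        (),
        len(inputs.genomes) >= 2 and len(inputs.proteomes) >= 2,
        do_metrics,
    )
    stage("ortholog_tree", (), len(inputs.proteomes) >= 3, do_tree)
    stage("hgt_screen", (), bool(inputs.hgt_proteome) and bool(inputs.hgt_hits), do_hgt)
    stage(
        "delineate",
        ("identity_16s", "genome_metrics"),
        inputs.focal in inputs.s16 and len(inputs.genomes) >= 2,
        do_delineate,
    )

    _write(run_dir / "manifest.json", json.dumps(manifest, indent=1, sort_keys=True))
    _write(run_dir / "run.log", "\n".join(log_lines) + "\n")
    return PipelineResult(run_dir=run_dir, manifest=manifest, verdict=state.get("verdict"))


def _cell(table, row, col):
    import math

    value = float(table.loc[row, col])
    return None if math.isnan(value) else value
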