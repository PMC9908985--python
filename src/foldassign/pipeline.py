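"""End-to-end orchestration: parse -> resolve -> chop -> QC -> assign ->
cluster -> triage, with full per-domain audit trail.

The run is deterministic for a fixed config and seed: inputs are processed
in sorted order, every artifact is written with stable formatting, and the
summary enforces count conservation (parsed domains = QC pass + QC fail;
QC pass = assigned + unassigned; unassigned = sum of cluster members), so
any bookkeeping drift fails loudly rather than producing silently wrong
headline numbers.
"""

from __future__ import annotations

import dataclasses
import json
import re
from collections import Counter, defaultdict
from dataclasses import dataclass, field
from pathlib import Path

from . import model_io
from .assignment import (AcceptanceThresholds, CascadeDecision, DomainLibrary,
                         LibraryEntry, PredictionRecord, TMAlignComparator,
                         cascade_assign)
from .clustering import all_vs_all, single_linkage, triage_cluster
from .model_io import FragmentSet, StructureModel, parse_model, write_domain
from .quality import QCReport, Thresholds, qc_verdict
from .resolution import (DomainRegion, UnchoppableError, choose_fragment,
                         chop, resolve_hits, MIN_DOMAIN_SIZE)

__all__ = ["RunConfig", "RunSummary", "run", "report", "load_library"]


@dataclass
class RunConfig:
    models_dir: str
    hits_path: str
    out_dir: str
    predictions_path: str = ""
    library_manifest: str = ""
    pdb_unclassified_manifest: str = ""
    thresholds: Thresholds = field(default_factory=Thresholds)
    acceptance: AcceptanceThresholds = field(default_factory=AcceptanceThresholds)
    overlap_tolerance: int = 10
    min_domain_size: int = MIN_DOMAIN_SIZE
    cluster_cutoff: float = 0.5
    do_assign: bool = True
    do_cluster: bool = True
    write_chopped: bool = True
    seed: int = 0

    def validate(self) -> None:
        for attr in ("models_dir", "hits_path"):
            p = getattr(self, attr)
            if not Path(p).exists():
                raise FileNotFoundError(f"{attr}: {p}")
        for attr in ("predictions_path", "library_manifest",
                     "pdb_unclassified_manifest"):
            p = getattr(self, attr)
            if p and not Path(p).exists():
                raise FileNotFoundError(f"{attr}: {p}")


@dataclass
class RunSummary:
    n_models: int = 0
    n_proteins: int = 0
    n_hits: int = 0
    n_selected_hits: int = 0
    n_rejected_hits: int = 0
    n_subsize_regions: int = 0
    n_unchoppable: int = 0
    n_chopped: int = 0
    n_qc_pass: int = 0
    n_qc_fail: int = 0
    qc_fail_by_rule: dict[str, int] = field(default_factory=dict)
    n_assigned: int = 0
    assigned_by_stage: dict[str, int] = field(default_factory=dict)
    by_source: dict[str, dict[str, int]] = field(default_factory=dict)
    n_unassigned: int = 0
    n_clusters: int = 0
    clusters_by_triage: dict[str, int] = field(default_factory=dict)
    n_clustered_members: int = 0

    def check_conservation(self) -> None:
        if self.n_chopped != self.n_qc_pass + self.n_qc_fail:
            raise AssertionError("chopped != qc_pass + qc_fail")
        if self.n_qc_pass != self.n_assigned + self.n_unassigned:
            raise AssertionError("qc_pass != assigned + unassigned")
        if self.n_unassigned != self.n_clustered_members:
            raise AssertionError("unassigned != clustered members")


def load_library(manifest: str | Path) -> list[LibraryEntry]:
    """Library manifest: ``domain_id <TAB> superfamily <TAB> pdb_path``
    (paths relative to the manifest's directory)."""
    manifest = Path(manifest)
    entries = []
    for line in manifest.read_text().splitlines():
        if not line.strip() or line.startswith("#"):
            continue
        did, sf, rel = line.split("\t")
        model = parse_model(manifest.parent / rel, protein_id=did)
        entries.append(LibraryEntry(did, sf, model))
    return sorted(entries, key=lambda e: e.domain_id)


def _load_predictions(path: str | Path) -> dict[str, PredictionRecord]:
    records = {}
    for line in Path(path).read_text().splitlines():
        if not line.strip() or line.startswith("#"):
            continue
        did, sf, prob = line.split("\t")
        records[did] = PredictionRecord(did, sf, float(prob))
    return records


def _discover_models(models_dir: str | Path) -> dict[str, dict[int, Path]]:
    """Map protein_id -> {fragment_index: path}. Fragmented proteins use the
    AFDB-style ``<id>-F<k>.pdb`` convention; anything else is fragment 1."""
    found: dict[str, dict[int, Path]] = defaultdict(dict)
    for path in sorted(Path(models_dir).glob("*.pdb")):
        stem = path.stem
        m = re.fullmatch(r"(.+)-F(\d+)", stem)
        if m:
            found[m.group(1)][int(m.group(2))] = path
        else:
            found[stem][1] = path
    return dict(found)


def run(config: RunConfig) -> RunSummary:
    """Execute the full protocol; artifacts land in ``config.out_dir``."""
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    (out / "config.json").write_text(json.dumps(
        {k: (dataclasses.asdict(v) if dataclasses.is_dataclass(v) else v)
         for k, v in dataclasses.asdict(config).items()},
        indent=1, sort_keys=True) + "\n")
    audit = open(out / "audit.jsonl", "w")

    def log(record: dict) -> None:
        audit.write(json.dumps(record, sort_keys=True) + "\n")

    summary = RunSummary()
    comparator = TMAlignComparator()

    # --- parse models -----------------------------------------------------
    model_paths = _discover_models(config.models_dir)
    models: dict[str, dict[int, StructureModel]] = {}
    fragsets: dict[str, FragmentSet] = {}
    for pid in sorted(model_paths):
        frags = {}
        for idx in sorted(model_paths[pid]):
            frags[idx] = parse_model(model_paths[pid][idx], protein_id=pid,
                                     fragment_index=idx)
            summary.n_models += 1
        models[pid] = frags
        ranges = [(idx, m.seq_indices[0], m.seq_indices[-1])
                  for idx, m in sorted(frags.items())]
        fragsets[pid] = FragmentSet(pid, ranges)
    summary.n_proteins = len(models)

    # --- resolve hits ------------------------------------------------------
    all_hits = model_io.load_hits(config.hits_path)
    summary.n_hits = len(all_hits)
    by_protein: dict[str, list] = defaultdict(list)
    for h in all_hits:
        by_protein[h.protein_id].append(h)
    resolved_rows = []
    regions: list[DomainRegion] = []
    for pid in sorted(by_protein):
        if pid not in models:
            for h in by_protein[pid]:
                summary.n_rejected_hits += 1
                resolved_rows.append((pid, h, "rejected", "no model on disk"))
            continue
        length = max(m.seq_indices[-1] for m in models[pid].values())
        layout = resolve_hits(by_protein[pid], config.overlap_tolerance,
                              protein_length=length)
        summary.n_selected_hits += len(layout.selected)
        summary.n_rejected_hits += len(layout.rejected)
        for h in layout.selected:
            region = DomainRegion.from_hit(h)
            if region.n_residues < config.min_domain_size:
                summary.n_subsize_regions += 1
                resolved_rows.append((pid, h, "rejected",
                                      "below minimum domain size"))
                continue
            resolved_rows.append((pid, h, "selected", ""))
            regions.append(region)
        for h, reason in layout.rejected:
            resolved_rows.append((pid, h, "rejected", reason))
    with open(out / "resolved.tsv", "w") as fh:
        fh.write("protein_id\tfamily_id\tscore\tsegments\tsource\tstatus\treason\n")
        for pid, h, status, reason in resolved_rows:
            fh.write("\t".join([pid, h.family_id or "-", f"{h.score:g}",
                                model_io.format_segments(h.segments),
                                h.source, status, reason]) + "\n")

    # --- chop --------------------------------------------------------------
    chopped: list[tuple[DomainRegion, StructureModel]] = []
    if config.write_chopped:
        (out / "chopped").mkdir(exist_ok=True)
    for region in sorted(regions, key=lambda r: (r.protein_id, r.start)):
        fragset = fragsets[region.protein_id]
        try:
            idx = choose_fragment(region, fragset)
        except UnchoppableError as exc:
            summary.n_unchoppable += 1
            log({"domain": region.domain_id, "stage": "chop",
                 "outcome": "unchoppable", "reason": str(exc)})
            continue
        domain_model = chop(models[region.protein_id][idx], region)
        domain_model = StructureModel(region.domain_id, domain_model.residues,
                                      fragment_index=idx)
        if config.write_chopped:
            write_domain(models[region.protein_id][idx], region,
                         path=out / "chopped" / f"{region.domain_id}.pdb")
        chopped.append((region, domain_model))
        summary.n_chopped += 1

    # --- QC ----------------------------------------------------------------
    qc_rows: list[QCReport] = []
    passing: list[tuple[DomainRegion, StructureModel]] = []
    src_counter: dict[str, Counter] = defaultdict(Counter)
    for region, dmodel in chopped:
        rep = qc_verdict(dmodel, config.thresholds, domain_id=region.domain_id)
        qc_rows.append(rep)
        src_counter[region.source]["chopped"] += 1
        log({"domain": region.domain_id, "stage": "qc",
             "outcome": rep.verdict, "failed_rules": rep.failed_rules,
             "mean_plddt": round(rep.mean_plddt, 3),
             "packing": None if rep.packing_density != rep.packing_density
             else round(rep.packing_density, 3)})
        if rep.verdict == "pass":
            summary.n_qc_pass += 1
            src_counter[region.source]["qc_pass"] += 1
            passing.append((region, dmodel))
        else:
            summary.n_qc_fail += 1
            for rule in rep.failed_rules:
                summary.qc_fail_by_rule[rule] = \
                    summary.qc_fail_by_rule.get(rule, 0) + 1
    with open(out / "qc_reports.tsv", "w") as fh:
        cols = ["domain_id", "mean_plddt", "n_residues",
                "max_single_lur_fraction", "unordered_fraction", "n_sses",
                "packing_density", "ses_area", "ses_volume",
                "ses_per_volume", "verdict", "failed_rules"]
        fh.write("\t".join(cols) + "\n")
        for r in qc_rows:
            fh.write("\t".join([
                r.domain_id, f"{r.mean_plddt:.3f}", str(r.n_residues),
                f"{r.max_single_lur_fraction:.4f}",
                f"{r.unordered_fraction:.4f}", str(r.n_sses),
                f"{r.packing_density:.4f}", f"{r.ses_area:.2f}",
                f"{r.ses_volume:.2f}", f"{r.ses_per_volume:.4f}",
                r.verdict, ",".join(r.failed_rules) or "-"]) + "\n")

    # --- cascade assignment -------------------------------------------------
    decisions: list[CascadeDecision] = []
    unassigned: list[tuple[DomainRegion, StructureModel]] = []
    peers: list[LibraryEntry] = []
    if config.do_assign and config.library_manifest:
        library = DomainLibrary(load_library(config.library_manifest))
        predictions = (_load_predictions(config.predictions_path)
                       if config.predictions_path else {})
        for region, dmodel in passing:
            candidate = (region.candidate_superfamily
                         if region.source in ("CATH-PDB", "CATH-HMM") else "")
            decision = cascade_assign(
                dmodel, library,
                prediction=predictions.get(region.domain_id),
                candidate_superfamily=candidate,
                comparator=comparator,
                thresholds=config.acceptance,
                peers=peers,
            )
            decisions.append(decision)
            log({"domain": region.domain_id, "stage": "assign",
                 "outcome": decision.stage,
                 "superfamily": decision.assigned_superfamily})
            if decision.stage == "unassigned":
                summary.n_unassigned += 1
                unassigned.append((region, dmodel))
            else:
                summary.n_assigned += 1
                src_counter[region.source]["assigned"] += 1
                summary.assigned_by_stage[decision.stage] = \
                    summary.assigned_by_stage.get(decision.stage, 0) + 1
                peers.append(LibraryEntry(region.domain_id,
                                          decision.assigned_superfamily,
                                          dmodel))
        with open(out / "decisions.tsv", "w") as fh:
            fh.write("domain_id\tstage\tsuperfamily\tscore\tscore_type\t"
                     "query_overlap\n")
            for d in decisions:
                hit = d.best_hit
                fh.write("\t".join([
                    d.query_id, d.stage, d.assigned_superfamily or "-",
                    f"{hit.score:.4f}" if hit else "-",
                    hit.score_type if hit else "-",
                    f"{hit.query_overlap:.3f}" if hit else "-"]) + "\n")
    else:
        unassigned = list(passing)
        summary.n_unassigned = len(unassigned)

    # --- clustering & triage -----------------------------------------------
    if config.do_cluster:
        domain_models = {r.domain_id: m for r, m in unassigned}
        edges = all_vs_all(domain_models, comparator,
                           edge_threshold=config.cluster_cutoff,
                           overlap_min=config.acceptance.overlap_min)
        clusters = single_linkage(edges, config.cluster_cutoff,
                                  all_ids=sorted(domain_models))
        pdb_lib = (load_library(config.pdb_unclassified_manifest)
                   if config.pdb_unclassified_manifest else [])
        assigned_lib = list(peers)
        if config.library_manifest and config.do_assign:
            assigned_lib = library.all() + assigned_lib
        for cluster in clusters:
            cluster.triage = triage_cluster(
                cluster, domain_models, pdb_lib, assigned_lib,
                comparator, config.acceptance)
            summary.clusters_by_triage[cluster.triage] = \
                summary.clusters_by_triage.get(cluster.triage, 0) + 1
            summary.n_clustered_members += cluster.size
        summary.n_clusters = len(clusters)
        with open(out / "clusters.tsv", "w") as fh:
            fh.write("cluster_id\tmember\ttriage\n")
            for i, c in enumerate(clusters):
                for m in c.members:
                    fh.write(f"c{i:04d}\t{m}\t{c.triage}\n")
        with open(out / "edges.tsv", "w") as fh:
            fh.write("id_a\tid_b\tweight\tpassed\n")
            for e in edges:
                fh.write(f"{e.id_a}\t{e.id_b}\t{e.weight:.4f}"
                         f"\t{int(e.passed)}\n")
    else:
        summary.n_clustered_members = summary.n_unassigned  # vacuous stage

    summary.by_source = {src: dict(cnt) for src, cnt in
                         sorted(src_counter.items())}
    if config.do_cluster or not config.do_assign:
        summary.check_conservation()
    audit.close()
    (out / "summary.json").write_text(json.dumps(
        dataclasses.asdict(summary), indent=1, sort_keys=True) + "\n")
    (out / "summary.tsv").write_text(report(summary))
    return summary


def report(summary: RunSummary) -> str:
    """Human-readable per-source breakdown; percentages are always derived
    from the stored counts. Refuses to render a non-conserving summary."""
    summary.check_conservation()
    lines = ["metric\tvalue"]
    for key in ("n_models", "n_proteins", "n_hits", "n_selected_hits",
                "n_rejected_hits", "n_subsize_regions", "n_unchoppable",
                "n_chopped", "n_qc_pass", "n_qc_fail", "n_assigned",
                "n_unassigned", "n_clusters"):
        lines.append(f"{key}\t{getattr(summary, key)}")
    if summary.n_chopped:
        pct = 100.0 * summary.n_qc_pass / summary.n_chopped
        lines.append(f"pct_qc_pass\t{pct:.1f}")
    if summary.n_qc_pass:
        pct = 100.0 * summary.n_assigned / summary.n_qc_pass
        lines.append(f"pct_assigned_of_confident\t{pct:.1f}")
    for rule, n in sorted(summary.qc_fail_by_rule.items()):
        lines.append(f"qc_fail[{rule}]\t{n}")
    for stage, n in sorted(summary.assigned_by_stage.items()):
        lines.append(f"assigned[{stage}]\t{n}")
    for triage, n in sorted(summary.clusters_by_triage.items()):
        lines.append(f"clusters[{triage}]\t{n}")
    for src, counts in summary.by_source.items():
        chopped = counts.get("chopped", 0)
        qc = counts.get("qc_pass", 0)
        asg = counts.get("assigned", 0)
        lines.append(f"source[{src}]\tchopped={chopped} qc_pass={qc} "
                     f"assigned={asg}")
    return "\n".join(lines) + "\n"
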