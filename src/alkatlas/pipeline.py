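"""End-to-end orchestration of the analysis stages from one YAML config.

Stage order: survey -> classify -> tree (cohort track); txunit -> elements
(locus track); decay; expression. Every stage writes plain files into the
output directory and registers them, with content hashes, in a manifest so
that a rerun with the same config and seed can be checked for reproducibility.
One global seed is fanned out to per-stage seeds by stable hashing.
"""

from __future__ import annotations

import hashlib
import json
import logging
import zlib
from pathlib import Path
from typing import Any, Optional

import numpy as np
import yaml

from . import locus as locus_mod
from .decay_kinetics import compare_half_lives, fit_decay, write_fits_csv
from .expression_meta import load_novobiocin_table, sign_concordance, top_change
from .genome_model import ProductClass, write_genome, write_tss_table
from .ortholog_survey import cooccurrence_summary, find_orthologs
from .phylo import distance_matrix, neighbor_joining, overlay_presence
from .regulatory_elements import find_terminator_hairpin, scan_minus10
from .synteny_classifier import Arrangement, classify_arrangement, cohort_stats
from .synthetic_data import (CohortSpec, DecaySpec, generate_alignment_on_tree,
                             generate_cohort, generate_decay_series,
                             seed_proteins, _revcomp)
from .txunit import (LengthEvidence, assign_tss, classify_transcript,
                     min_dicistron_length, reconstruct_circular_junction,
                     utr_lengths)

logger = logging.getLogger(__name__)

STAGE_ORDER = ["survey", "classify", "tree", "txunit", "elements",
               "decay", "expression"]
_DEPS = {"classify": "survey", "tree": "classify"}

DEFAULT_CONFIG: dict[str, Any] = {
    "seed": 1,
    "outdir": "alkatlas_out",
    "stages": list(STAGE_ORDER),
    "evalue": 1e-5,
    "max_gap_nt": 500,
    "max_intervening_genes": 1,
    "max_leader_nt": 300,
    "cohort": {
        "n_genomes": 20,
        "frequencies": {"FIVE_GENE_CLUSTER": 0.61, "TANDEM_PAIR": 0.15,
                        "SPLIT": 0.14, "ABSENT": 0.10},
        "identity": 0.9,
    },
    "tree": {"seq_len": 1500},
    "decay": {"half_lives": {"SyR9": 2.2, "ado": 1.8, "aar": 1.6},
              "noise_sd_log": 0.0},
}


def stage_seed(global_seed: int, stage: str) -> int:
    """Stable per-stage seed below 2**31."""
    return zlib.crc32(f"{global_seed}:{stage}".encode()) & 0x7FFFFFFF


def _load_config(config) -> dict[str, Any]:
    if isinstance(config, (str, Path)):
        with open(config) as fh:
            config = yaml.safe_load(fh) or {}
    merged = json.loads(json.dumps(DEFAULT_CONFIG))
    for key, val in config.items():
        if isinstance(val, dict) and isinstance(merged.get(key), dict):
            merged[key].update(val)
        else:
            merged[key] = val
    return merged


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _random_tree_newick(taxa: list[str], rng: np.random.Generator) -> str:
    """Random binary topology with exponential branch lengths."""
    def build(group: list[str]) -> str:
        if len(group) == 1:
            return f"{group[0]}:{rng.exponential(0.05) + 0.01:.6f}"
        k = int(rng.integers(1, len(group)))
        left, right = group[:k], group[k:]
        return (f"({build(left)},{build(right)})"
                f":{rng.exponential(0.05) + 0.01:.6f}")
    order = list(taxa)
    rng.shuffle(order)
    return f"({build(order[: len(order) // 2])},{build(order[len(order) // 2:])});"


def run_pipeline(config=None) -> dict[str, Any]:
    """Run the configured stages; return (and write) the output manifest."""
    cfg = _load_config(config or {})
    outdir = Path(cfg["outdir"])
    outdir.mkdir(parents=True, exist_ok=True)
    seed = int(cfg["seed"])
    stages = [s for s in STAGE_ORDER if s in cfg["stages"]]
    for s in stages:
        dep = _DEPS.get(s)
        if dep and dep not in stages:
            raise ValueError(f"stage {s!r} requires stage {dep!r} to be enabled")
    logger.info("thresholds: evalue=%g max_gap_nt=%d max_intervening_genes=%d "
                "max_leader_nt=%d", cfg["evalue"], cfg["max_gap_nt"],
                cfg["max_intervening_genes"], cfg["max_leader_nt"])

    manifest: dict[str, Any] = {"seed": seed, "config": cfg, "stages": {}}
    ctx: dict[str, Any] = {}
    runners = {
        "survey": _run_survey, "classify": _run_classify, "tree": _run_tree,
        "txunit": _run_txunit, "elements": _run_elements,
        "decay": _run_decay, "expression": _run_expression,
    }
    for stage in stages:
        try:
            files, summary = runners[stage](cfg, ctx, outdir,
                                            stage_seed(seed, stage))
        except Exception as exc:
            raise RuntimeError(f"stage {stage!r} failed: {exc}") from exc
        manifest["stages"][stage] = {
            "files": {str(p.relative_to(outdir)): _sha256(p) for p in files},
            "summary": summary,
        }
    manifest_path = outdir / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=2, default=str))
    return manifest


# ---------------------------------------------------------------------------
# stage runners: each returns (written files, JSON-safe summary)
# ---------------------------------------------------------------------------

def _run_survey(cfg, ctx, outdir: Path, seed: int):
    cc = cfg["cohort"]
    spec = CohortSpec(
        n_genomes=int(cc["n_genomes"]),
        arrangement_frequencies={Arrangement[k]: float(v)
                                 for k, v in cc["frequencies"].items()},
        ortholog_identity=float(cc["identity"]),
        seed=seed,
    )
    cohort = generate_cohort(spec)
    queries = seed_proteins()
    profiles = [find_orthologs(g, queries, threshold_evalue=float(cfg["evalue"]))
                for g in cohort.genomes]
    ctx["cohort"], ctx["profiles"] = cohort, profiles
    path = outdir / "survey.tsv"
    with open(path, "w") as fh:
        fh.write("genome_id\tproduct_class\tgene_id\traw_score\tevalue\n")
        for p in profiles:
            for cls in ProductClass:
                if cls is ProductClass.OTHER:
                    continue
                h = p.detected.get(cls)
                if h:
                    fh.write(f"{p.genome_id}\t{cls.value}\t{h.subject_gene_id}"
                             f"\t{h.raw_score:g}\t{h.evalue:.3g}\n")
                else:
                    fh.write(f"{p.genome_id}\t{cls.value}\t-\t-\t-\n")
    co = cooccurrence_summary(profiles)
    return [path], {"n_genomes": len(profiles), "cooccurrence": co}


def _run_classify(cfg, ctx, outdir: Path, seed: int):
    cohort, profiles = ctx["cohort"], ctx["profiles"]
    calls = [classify_arrangement(g, p, int(cfg["max_gap_nt"]),
                                  int(cfg["max_intervening_genes"]))
             for g, p in zip(cohort.genomes, profiles)]
    ctx["calls"] = calls
    path = outdir / "arrangements.tsv"
    with open(path, "w") as fh:
        fh.write("genome_id\tarrangement\ttruth\tevidence\n")
        for c in calls:
            fh.write(f"{c.genome_id}\t{c.arrangement.value}"
                     f"\t{cohort.truth[c.genome_id].value}\t{c.evidence}\n")
    stats = cohort_stats(calls)
    recovery = sum(c.arrangement is cohort.truth[c.genome_id] for c in calls
                   ) / len(calls)
    summary = {"fraction_both_present": stats.fraction_both_present,
               "fraction_tandem": stats.fraction_tandem,
               "fraction_five_gene_cluster": stats.fraction_five_gene_cluster,
               "count_absent": stats.count_absent,
               "label_recovery": recovery}
    spath = outdir / "cohort_summary.json"
    spath.write_text(json.dumps(summary, indent=2))
    return [path, spath], summary


def _run_tree(cfg, ctx, outdir: Path, seed: int):
    calls = ctx["calls"]
    rng = np.random.default_rng(seed)
    taxa = [c.genome_id for c in calls]
    newick = _random_tree_newick(taxa, rng)
    aln = generate_alignment_on_tree(newick, int(cfg["tree"]["seq_len"]),
                                     seed=seed)
    dm = distance_matrix(aln, model="jukes_cantor")
    tree = neighbor_joining(dm)
    annotated = overlay_presence(tree, calls)
    tpath = outdir / "tree.nwk"
    tpath.write_text(annotated.newick() + "\n")
    lpath = outdir / "tree_legend.tsv"
    with open(lpath, "w") as fh:
        fh.write("genome_id\tarrangement\n")
        for leaf, lab in annotated.labels.items():
            fh.write(f"{leaf}\t{lab}\n")
    return [tpath, lpath], {"n_taxa": len(taxa),
                            "absent_group_count": annotated.absent_group_count}


def _run_txunit(cfg, ctx, outdir: Path, seed: int):
    demo = locus_mod.build_demo_genome(seed=seed)
    ctx["demo"] = demo
    genes = demo.genome.features
    off = demo.offset
    assigned, orphans = assign_tss(demo.tss, genes,
                                   max_leader_nt=int(cfg["max_leader_nt"]))
    junctions = {
        "SyR9_ado_cotranscript": tuple(x - off for x in locus_mod.COTRANSCRIPT_JUNCTION),
        "aar_mRNA": tuple(x - off for x in locus_mod.AAR_JUNCTION),
    }
    rows, bed = [], []
    for name, junc in junctions.items():
        model = reconstruct_circular_junction(junc, "-")
        cls = classify_transcript(model, genes, srna_loci=[demo.srna])
        covered = [g for g in genes
                   if model.span[0] <= g.start and g.end <= model.span[1]]
        utr_note = ""
        if len(covered) == 1:
            u5, u3 = utr_lengths(model, covered[0])
            utr_note = f"utr5={u5};trailer={u3}"
        rows.append((name, model.length_nt, cls.value, utr_note))
        lo, hi = model.span
        bed.append(f"demo\t{lo - 1}\t{hi}\t{name}\t0\t-")
    ado = next(g for g in genes if g.product_class is ProductClass.ADO)
    aar = next(g for g in genes if g.product_class is ProductClass.AAR)
    bound = min_dicistron_length(ado, aar)
    rpath = outdir / "transcripts.tsv"
    with open(rpath, "w") as fh:
        fh.write("transcript\tlength_nt\tclass\tnotes\n")
        for name, ln, cls, note in rows:
            fh.write(f"{name}\t{ln}\t{cls}\t{note}\n")
        fh.write(f"min_dicistron_bound\t{bound}\t-\tado start to aar stop\n")
    bpath = outdir / "transcripts.bed"
    bpath.write_text("\n".join(bed) + "\n")
    tsspath = outdir / "tss.tsv"
    write_tss_table(demo.tss, tsspath)
    gff = outdir / "demo_locus.gff3"
    fasta = outdir / "demo_locus.fa"
    write_genome(demo.genome, gff, fasta)
    summary = {
        "transcripts": {name: {"length_nt": ln, "class": cls}
                        for name, ln, cls, _ in rows},
        "min_dicistron_bound_nt": bound,
        "tss_assignments": {g: [(a.tss.label, a.leader_nt, a.role) for a in lst]
                            for g, lst in assigned.items()},
        "orphan_tss": [t.label for t in orphans],
    }
    return [rpath, bpath, tsspath, gff, fasta], summary


def _run_elements(cfg, ctx, outdir: Path, seed: int):
    demo = ctx.get("demo") or locus_mod.build_demo_genome(seed=stage_seed(
        int(cfg["seed"]), "txunit"))
    seq = demo.genome.contigs["demo"]
    gff_rows = []
    promoter_summary = {}
    for tss in demo.tss:
        call = scan_minus10(seq, tss)
        if call is None:
            promoter_summary[tss.label] = None
            continue
        lo = tss.position - call.hexamer_offset
        hi = lo + 5
        gff_rows.append(f"demo\talkatlas\tminus10_element\t{lo}\t{hi}\t"
                        f"{call.score:.2f}\t-\t.\tID=minus10_{tss.label};"
                        f"hexamer={call.hexamer_seq};offset={call.hexamer_offset}")
        promoter_summary[tss.label] = {"hexamer": call.hexamer_seq,
                                       "offset": call.hexamer_offset,
                                       "score": round(call.score, 2)}
    lo, hi = demo.terminator_region
    region_rc = _revcomp(seq[lo - 1:hi])
    term = find_terminator_hairpin(region_rc)
    term_summary = None
    if term:
        g_hi = hi - (term.start - 1)
        g_lo = hi - (term.end - 1)
        gff_rows.append(f"demo\talkatlas\tterminator\t{g_lo}\t{g_hi}\t"
                        f"{term.pairing_score:.1f}\t-\t.\tID=ado_terminator;"
                        f"stem={term.stem_len};loop={term.loop_len};"
                        f"u_tract={term.u_tract_len}")
        term_summary = {"stem_len": term.stem_len, "loop_len": term.loop_len,
                        "u_tract_len": term.u_tract_len,
                        "score": term.pairing_score}
    path = outdir / "elements.gff3"
    path.write_text("##gff-version 3\n" + "\n".join(gff_rows) + "\n")
    return [path], {"minus10": promoter_summary, "terminator": term_summary}


def _run_decay(cfg, ctx, outdir: Path, seed: int):
    dc = cfg["decay"]
    fits = []
    for i, (tid, hl) in enumerate(dc["half_lives"].items()):
        spec = DecaySpec(initial_signal=100.0, half_life_min=float(hl),
                         noise_sd_log=float(dc["noise_sd_log"]),
                         seed=seed + i, transcript_id=tid)
        fits.append(fit_decay(generate_decay_series(spec)))
    report = compare_half_lives(fits, list(dc["half_lives"]))
    path = outdir / "decay_fits.csv"
    write_fits_csv(fits, path)
    return [path], {
        "half_lives_min": {f.transcript_id: round(f.half_life_min, 4)
                           for f in fits},
        "ordering_ok": report.ordered_ok,
        "all_below_3min": report.below_cap,
    }


def _run_expression(cfg, ctx, outdir: Path, seed: int):
    table = load_novobiocin_table()
    summary = {}
    for gene in ("ado", "aar"):
        cond_max, v_max = top_change(table, gene, "max")
        cond_min, v_min = top_change(table, gene, "min")
        summary[gene] = {"max": [cond_max, v_max], "min": [cond_min, v_min]}
    conc, discordant = sign_concordance(table, "ado", "aar")
    summary["sign_concordance"] = conc
    summary["discordant_conditions"] = discordant
    path = outdir / "expression_summary.json"
    path.write_text(json.dumps(summary, indent=2))
    return [path], summary
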