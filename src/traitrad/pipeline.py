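"""End-to-end orchestration: homolog search through cluster detection.

``refine_homolog_tree`` runs the iterative alignment/estimation loop
(align, trim at 0.01, tree; realign, trim at 0.05, tree, prune
branches > 1.5, extract the anchored clade; realign, drop poorly
aligned rows, trim at 0.1, tree, prune tips > 1.0, final tree with
bootstrap).  ``run_all`` chains search, refinement, rooting,
reconciliation, presence/loss summaries, trait ASR, codon filtering,
branch-site selection, diagnostic residues and cluster detection into
one auditable report.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Iterable, Optional

import numpy as np

from . import msa
from .asr import fit_mk1
from .diagnostics import diagnostic_sites, gene_clusters
from .iocore import (Alignment, CodonAlignment, FormatError, Sequence,
                     TipSpeciesMap, TraitTable, read_fasta, read_gff3,
                     read_trait_csv, write_alignment_fasta)
from .protmodel import SubstitutionModel, distance_matrix
from .reconcile import (lca_reconcile, loss_asymmetry, presence_matrix)
from .search import SearchParams, find_homologs
from .selection import eb_site_posteriors, fit_codon_model, lrt
from .surgery import (extract_anchored_clade, prune_long_branches,
                      prune_long_tips, root_with_outgroup)
from .tree import Tree, TreeError
from .treeinfer import bootstrap_support, ml_refine, nj_tree


@dataclass
class PipelineConfig:
    """Parameters for the full analysis; defaults follow the method's
    published settings (identity 0.40, E-value 10, occupancy trims
    0.01/0.05/0.1, branch prune 1.5, tip prune 1.0, BEB threshold
    0.95)."""

    anchor_id: str = ""
    outgroup_species: list = field(default_factory=list)
    clade_tips: dict = field(default_factory=dict)   # name -> gene tip list
    focal_genes: tuple = ()
    # search
    min_identity: float = 0.40
    evalue_max: float = 10.0
    # refinement loop
    trim_occupancies: tuple = (0.01, 0.05, 0.1)
    prune_branch: float = 1.5
    prune_tip: float = 1.0
    min_seq_coverage: float = 0.5
    extract_clade: bool = True
    n_outgroup_lineages: int = 1
    max_nni_rounds: int = 2
    bootstrap_reps: int = 100
    # codon analyses
    window: Optional[tuple] = None          # (first, last) ref codons
    selection_foreground: Optional[str] = None  # clade name
    n_starts: int = 1
    beb_threshold: float = 0.95
    # diagnostics
    diagnostic_mode: str = "tolerant"
    diagnostic_tau: float = 0.1
    cluster_max_distance: int = 50000
    # machinery
    seed: int = 0
    stages: tuple = ("search", "refine", "reconcile", "asr", "selection",
                     "diagnostics", "clusters")
    outdir: Optional[str] = None


@dataclass
class PipelineInputs:
    proteins: list                          # Sequence
    cds: list = field(default_factory=list)
    species_tree: Optional[Tree] = None
    traits: Optional[TraitTable] = None
    annotations: list = field(default_factory=list)

    @classmethod
    def from_paths(cls, proteins=None, cds=None, species_tree=None,
                   traits=None, gff=None) -> "PipelineInputs":
        return cls(
            proteins=read_fasta(proteins, "protein") if proteins else [],
            cds=read_fasta(cds, "cds") if cds else [],
            species_tree=Tree.read(species_tree) if species_tree else None,
            traits=read_trait_csv(traits) if traits else None,
            annotations=read_gff3(gff) if gff else [])


@dataclass
class RunReport:
    """Consolidated machine-readable record of every stage."""

    stages: dict = field(default_factory=dict)
    final_alignment: Optional[Alignment] = None
    final_tree: Optional[Tree] = None

    def to_json(self) -> str:
        return json.dumps(self.stages, indent=1, sort_keys=True,
                          default=_jsonable)

    def summary(self) -> str:
        lines = ["# pipeline run", ""]
        for name, rec in self.stages.items():
            lines.append(f"## {name}")
            for k, v in rec.items():
                if isinstance(v, (int, float, str, bool)):
                    lines.append(f"- {k}: {v}")
            lines.append("")
        return "\n".join(lines)


def _jsonable(x):
    if isinstance(x, (np.integer,)):
        return int(x)
    if isinstance(x, (np.floating,)):
        return float(x)
    if isinstance(x, np.ndarray):
        return x.tolist()
    if isinstance(x, (set, frozenset, tuple)):
        return sorted(x) if isinstance(x, (set, frozenset)) else list(x)
    return str(x)


def _estimate_tree(aln: Alignment, model: SubstitutionModel,
                   max_nni_rounds: int) -> Tree:
    if aln.n_rows < 3:
        raise TreeError("tree estimation needs at least 3 sequences")
    start = nj_tree(distance_matrix(aln, model))
    return ml_refine(start, aln, model, max_nni_rounds=max_nni_rounds)


def refine_homolog_tree(seqs: list[Sequence], config: PipelineConfig,
                        record: Optional[dict] = None) -> tuple[Alignment, Tree]:
    """The iterative alignment/tree-estimation/pruning loop."""
    record = record if record is not None else {}
    model = SubstitutionModel()
    anchor = config.anchor_id
    if anchor and anchor not in {s.id for s in seqs}:
        raise TreeError(f"anchor {anchor!r} not among the input sequences")
    occ1, occ2, occ3 = config.trim_occupancies
    by_id = {s.id: s for s in seqs}

    def realign(ids: Iterable[str]) -> Alignment:
        return msa.progressive_align([by_id[i] for i in ids])

    # round 1: align, trim low-occupancy, first tree
    aln = msa.progressive_align(seqs)
    dropped_cols: list = []
    aln = msa.trim_columns(aln, occ1, removed=dropped_cols)
    record["trim1_removed_columns"] = len(dropped_cols)
    tree = _estimate_tree(aln, model, config.max_nni_rounds)

    # round 2: realign, trim, tree, prune long branches, extract clade
    aln = realign(aln.ids)
    dropped_cols = []
    aln = msa.trim_columns(aln, occ2, removed=dropped_cols)
    record["trim2_removed_columns"] = len(dropped_cols)
    tree = _estimate_tree(aln, model, config.max_nni_rounds)
    removed_tips: list = []
    tree = prune_long_branches(tree, config.prune_branch, anchor,
                               removed=removed_tips)
    record["pruned_long_branch_tips"] = list(removed_tips)
    og_tips = [t for t in tree.tip_labels()
               if _species(t) in config.outgroup_species]
    if config.extract_clade and anchor and og_tips:
        base = root_with_outgroup(tree, og_tips)
        all_named = {t for tips in config.clade_tips.values() for t in tips}
        target = None
        if anchor in all_named:
            target = [t for t in all_named if t in base.tip_labels()]
        if target:
            core = base.mrca(set(target) | {anchor})
            # widen by the closest outgroup lineages
            for _ in range(config.n_outgroup_lineages):
                if core.parent is not None:
                    core = core.parent
            tree = extract_anchored_clade(
                base, anchor, target_tips=[t.label for t in core.leaves()])
        else:
            tree = extract_anchored_clade(
                base, anchor,
                n_outgroup_lineages=config.n_outgroup_lineages)
        record["extracted_clade_size"] = tree.n_tips

    # round 3: realign survivors, drop poorly aligned, trim, tree,
    # prune long tips, final tree with bootstrap
    aln = realign(tree.tip_labels())
    removed_rows: list = []
    if aln.n_rows > 3:
        aln = msa.remove_poorly_aligned(aln, config.min_seq_coverage,
                                        removed=removed_rows)
    record["removed_poorly_aligned"] = list(removed_rows)
    dropped_cols = []
    aln = msa.trim_columns(aln, occ3, removed=dropped_cols)
    record["trim3_removed_columns"] = len(dropped_cols)
    tree = _estimate_tree(aln, model, config.max_nni_rounds)
    removed_tips = []
    tree = prune_long_tips(tree, config.prune_tip, removed=removed_tips)
    record["pruned_long_tip_ids"] = list(removed_tips)
    if removed_tips:
        aln = aln.subset_rows(tree.tip_labels())
    if anchor and anchor not in tree.tip_labels():
        raise TreeError("anchor was eliminated during refinement")
    tree = bootstrap_support(aln, model, n_reps=config.bootstrap_reps,
                             seed=config.seed, reference=tree)
    record["final_n_tips"] = tree.n_tips
    record["final_n_columns"] = aln.n_columns
    return aln, tree


def _species(tip_label: str) -> str:
    return TipSpeciesMap()(tip_label)


def run_all(inputs: PipelineInputs, config: PipelineConfig) -> RunReport:
    """Execute the configured stages and assemble the run report."""
    report = RunReport()
    stages = set(config.stages)
    if not inputs.proteins:
        raise FormatError("pipeline requires protein sequences")
    seqs = inputs.proteins

    if "search" in stages:
        if not config.anchor_id:
            raise FormatError("search stage needs an anchor/query id")
        query = next(s for s in seqs if s.id == config.anchor_id)
        params = SearchParams(min_identity=config.min_identity,
                              evalue_max=config.evalue_max)
        hits = find_homologs(query, seqs, params)
        keep = {h.target_id for h in hits}
        report.stages["search"] = {
            "query": query.id, "database_size": len(seqs),
            "n_hits": len(hits), "min_identity": config.min_identity,
            "evalue_max": config.evalue_max,
            "hit_ids": sorted(keep)}
        seqs = [s for s in seqs if s.id in keep]

    aln = tree = rooted = None
    if "refine" in stages:
        rec: dict = {}
        aln, tree = refine_homolog_tree(seqs, config, record=rec)
        report.stages["refine"] = rec
        report.final_alignment = aln
        og_tips = [t for t in tree.tip_labels()
                   if _species(t) in config.outgroup_species]
        if og_tips:
            rooted = root_with_outgroup(tree, og_tips)
        elif tree.rooted:
            rooted = tree
        else:
            # fall back: root on the tip farthest from the anchor
            from .tree import path_length
            far = max((t for t in tree.tip_labels()
                       if t != config.anchor_id),
                      key=lambda t: path_length(tree, config.anchor_id, t))
            rooted = tree.reroot_on_edge(tree.find_tip(far))
        report.final_tree = rooted

    if "reconcile" in stages and rooted is not None and \
            inputs.species_tree is not None:
        recon = lca_reconcile(rooted, inputs.species_tree)
        placements = {}
        for i, g in enumerate(recon.duplication_nodes, 1):
            sp, _sp_parent = recon.placement_edge(g)
            placements[g.label or f"dup{i:02d}"] = sp.label
        rec = {"n_duplications": recon.n_duplications,
               "placements": placements}
        clades_in = {name: [t for t in tips if t in rooted.tip_labels()]
                     for name, tips in config.clade_tips.items()}
        clades_in = {k: v for k, v in clades_in.items() if v}
        if clades_in:
            for name, tips in clades_in.items():
                mrca = rooted.mrca(tips)
                rec[f"{name}_clade_duplications"] = sum(
                    1 for d in recon.duplication_nodes
                    if id(d) in {id(x) for x in mrca.postorder()})
            pm = presence_matrix(
                rooted, clades_in, inputs.species_tree.tip_labels(),
                traits=inputs.traits)
            rec["presence"] = {
                name: sorted(pm.table.index[pm.table[name]])
                for name in clades_in}
            if inputs.traits is not None and len(clades_in) >= 2:
                names = sorted(clades_in)
                for state in ("anthocyanin", "betalain"):
                    sp_state = [s for s in pm.table.index
                                if pm.trait_states.get(s) == state]
                    if sp_state:
                        la = loss_asymmetry(pm, names[0], names[1], state)
                        rec[f"loss_asymmetry_{state}"] = {
                            "table": la.table, "p_value": la.p_value}
        report.stages["reconcile"] = rec

    if "asr" in stages and inputs.species_tree is not None and \
            inputs.traits is not None:
        fit = fit_mk1(inputs.species_tree, inputs.traits)
        pies = {rec["node"].label or "root":
                [round(p, 6) for p in rec["posterior"]]
                for rec in fit.node_posteriors.values()}
        report.stages["asr"] = {
            "rate": fit.rate, "logL": fit.logL, "neg_logL": fit.neg_logL,
            "at_boundary": fit.at_boundary, "node_posteriors": pies}

    if "selection" in stages and aln is not None and inputs.cds:
        rec = {}
        caln = msa.backtranslate(aln, inputs.cds)
        if config.window:
            first, last = config.window
            caln_rows = msa.window_complete_filter(
                Alignment(caln.ids, caln.rows, kind="nucleotide"),
                first, last, config.anchor_id)
            caln = CodonAlignment(caln_rows.ids, caln_rows.rows)
        removed_cols: list = []
        caln = msa.clean_codon_columns(caln, removed=removed_cols)
        rec["clean_removed_codons"] = len(removed_cols)
        fg_name = config.selection_foreground
        fg_tips = [t for t in config.clade_tips.get(fg_name, [])
                   if t in caln.ids]
        if len(fg_tips) >= 2 and rooted is not None:
            sel_tree = rooted
            if set(sel_tree.tip_labels()) != set(caln.ids):
                keep = [t for t in sel_tree.tip_labels() if t in caln.ids]
                caln = CodonAlignment(
                    *zip(*[(i, r) for i, r in zip(caln.ids, caln.rows)
                           if i in keep]))
                caln = CodonAlignment(list(caln.ids), list(caln.rows))
            alt = fit_codon_model(sel_tree, caln, "modelA",
                                  foreground_tips=fg_tips,
                                  n_starts=config.n_starts,
                                  seed=config.seed)
            null = fit_codon_model(sel_tree, caln, "modelA_null",
                                   foreground_tips=fg_tips,
                                   n_starts=config.n_starts,
                                   seed=config.seed,
                                   start_params={**alt.params, "omega2": 1.0})
            test = lrt(null, alt, mixture=True)
            post = eb_site_posteriors(alt, sel_tree, caln, method="BEB")
            rec.update({
                "model": "modelA", "foreground": fg_name,
                "logL_alt": alt.logL, "logL_null": null.logL,
                "kappa": alt.params["kappa"],
                "omega0": alt.params["omega0"],
                "omega2": alt.params.get("omega2"),
                "lrt_statistic": test.statistic, "lrt_p": test.p_value,
                "selected_sites_0.95": post.selected_sites(0.95),
                "selected_sites_0.99": post.selected_sites(0.99)})
        report.stages["selection"] = rec

    if "diagnostics" in stages and aln is not None and \
            len(config.clade_tips) >= 2:
        names = sorted(config.clade_tips)
        a_ids = [t for t in config.clade_tips[names[0]] if t in aln.ids]
        b_ids = [t for t in config.clade_tips[names[1]] if t in aln.ids]
        if len(a_ids) >= 2 and len(b_ids) >= 2:
            sites = diagnostic_sites(
                aln, a_ids, b_ids, config.anchor_id,
                mode=config.diagnostic_mode, tau=config.diagnostic_tau)
            report.stages["diagnostics"] = {
                "cladeA": names[0], "cladeB": names[1],
                "n_sites": len(sites),
                "sites": [{"column": s.column,
                           "reference_position": s.reference_position,
                           "residue_a": s.cladeA_residue,
                           "majority_b": s.cladeB_majority,
                           "strict": s.strict} for s in sites]}

    if "clusters" in stages and inputs.annotations and config.focal_genes:
        rep = gene_clusters(inputs.annotations, tuple(config.focal_genes),
                            max_distance=config.cluster_max_distance)
        report.stages["clusters"] = {
            "gene_a": rep.gene_a, "gene_b": rep.gene_b,
            "chromosome": rep.chromosome, "distance": rep.distance,
            "intervening_genes": rep.intervening_genes,
            "within_threshold": rep.within_threshold,
            "linked": rep.linked}

    if config.outdir:
        out = Path(config.outdir)
        out.mkdir(parents=True, exist_ok=True)
        (out / "report.json").write_text(report.to_json())
        (out / "report.md").write_text(report.summary())
        if report.final_alignment is not None:
            write_alignment_fasta(report.final_alignment,
                                  out / "final_alignment.fasta")
        if report.final_tree is not None:
            report.final_tree.write(out / "final_tree.nwk")
    return report
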