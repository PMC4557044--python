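"""Validation experiments: parameter recovery, test calibration and
truth recovery on synthetic data.

These are the package's standard self-checks: each function simulates
under known truth with the package's own generator and measures how
well the inference machinery recovers it.  They are deliberately
desk-scale (tens of replicates, hundreds of sites) so a full battery
runs in minutes.
"""

from __future__ import annotations

from dataclasses import replace
from typing import Optional

import numpy as np

from .asr import fit_mk1
from .iocore import TraitTable
from .pipeline import PipelineConfig, PipelineInputs, run_all
from .selection import eb_site_posteriors, fit_codon_model, lrt
from .simulate import (CodonSimParams, ScenarioConfig, generate_scenario,
                       simulate_codon_alignment, simulate_species_tree,
                       simulate_trait)
from .tree import Tree

#: fixed 6-taxon experiment tree (unrooted; lengths in subst./codon)
SIX_TAXON_TREE = ("((A:0.3,B:0.3):0.15,(C:0.3,D:0.3):0.15,"
                  "(E:0.3,F:0.3):0.15);")

#: tree for site-detection experiments: an 8-tip foreground radiation
#: (total foreground length ~4 subst./codon) against 4 background taxa,
#: so individual selected sites accumulate enough foreground changes
#: for empirical-Bayes identification
FOREGROUND_RADIATION_TREE = (
    "(((((A:0.4,B:0.4):0.2,(A2:0.4,B2:0.4):0.2):0.2,"
    "((A3:0.4,B3:0.4):0.2,(A4:0.4,B4:0.4):0.2):0.2):0.3,"
    "(C:0.4,D:0.4):0.3):0.1,(E:0.5,F:0.5):0.2);")

FOREGROUND_TIPS = ("A", "B", "A2", "B2", "A3", "B3", "A4", "B4")


def _experiment_tree() -> Tree:
    return Tree.from_newick(SIX_TAXON_TREE)


def mk1_rate_recovery(n_reps: int = 100, n_tips: int = 300,
                      true_rate: float = 1.0, seed: int = 0) -> np.ndarray:
    """Mk1 rate estimates over forward-simulated trait replicates."""
    out = []
    for rep in range(n_reps):
        tree = simulate_species_tree(n_tips, seed=seed * 100003 + rep,
                                     height=1.0)
        traits, _ = simulate_trait(tree, true_rate,
                                   seed=seed * 100003 + rep)
        states = set(traits.states.values())
        if len(states - {"missing"}) < 2:
            out.append(np.nan)  # degenerate draw: boundary MLE
            continue
        fit = fit_mk1(tree, traits, compute_posteriors=False)
        out.append(fit.rate)
    return np.asarray(out)


def m0_omega_recovery(n_seeds: int = 20, n_codons: int = 500,
                      true_omega: float = 0.2, kappa: float = 2.0,
                      seed: int = 0) -> np.ndarray:
    """M0 omega estimates on data simulated under M0."""
    tree = _experiment_tree()
    params = CodonSimParams(kappa=kappa, omega0=true_omega, omega2=1.0,
                            p0=1.0 - 1e-9, p1=0.0, n_codons=n_codons)
    out = []
    for rep in range(n_seeds):
        caln, _ = simulate_codon_alignment(tree, params,
                                           seed=seed * 7919 + rep)
        fit = fit_codon_model(tree, caln, "M0", n_starts=1,
                              seed=rep, codon_freqs="equal")
        out.append(fit.params["omega"])
    return np.asarray(out)


def branch_site_omega2_recovery(n_seeds: int = 20, n_codons: int = 500,
                                true_omega2: float = 5.0,
                                p2: float = 0.1,
                                seed: int = 0) -> np.ndarray:
    """Model-A omega2 estimates under a branch-site simulation."""
    tree = _experiment_tree()
    p01 = 1.0 - p2
    params = CodonSimParams(kappa=2.0, omega0=0.2, omega2=true_omega2,
                            p0=p01 / 2, p1=p01 / 2, n_codons=n_codons)
    fg = ["A", "B"]
    out = []
    for rep in range(n_seeds):
        caln, _ = simulate_codon_alignment(tree, params,
                                           foreground_clade=fg,
                                           seed=seed * 7919 + rep)
        fit = fit_codon_model(tree, caln, "modelA", foreground_tips=fg,
                              n_starts=1, seed=rep, codon_freqs="equal")
        out.append(fit.params["omega2"])
    return np.asarray(out)


def lrt_calibration(n_reps: int = 100, n_codons: int = 300,
                    alpha: float = 0.05, seed: int = 0) -> dict:
    """M2a-vs-M1a type-I error on M1a-simulated data.

    The chi-square(2) reference is conservative at this boundary, so
    the empirical rejection rate should sit at or below the nominal
    level.
    """
    tree = _experiment_tree()
    params = CodonSimParams(kappa=2.0, omega0=0.2, omega2=1.0,
                            p0=0.7, p1=0.3, n_codons=n_codons)
    pvals = []
    for rep in range(n_reps):
        caln, _ = simulate_codon_alignment(tree, params,
                                           seed=seed * 7919 + rep)
        null = fit_codon_model(tree, caln, "M1a", n_starts=1, seed=rep,
                               codon_freqs="equal")
        alt_start = {"kappa": null.params["kappa"],
                     "omega0": null.params["omega0"],
                     "p0": null.params["p0"] * 0.98,
                     "p1": (1 - null.params["p0"]) * 0.98,
                     "omega2": 1.5}
        alt = fit_codon_model(tree, caln, "M2a", n_starts=1, seed=rep,
                              codon_freqs="equal", start_params=alt_start)
        if alt.logL < null.logL:  # numerically flat: statistic is 0
            pvals.append(1.0)
        else:
            pvals.append(lrt(null, alt).p_value)
    pvals = np.asarray(pvals)
    return {"p_values": pvals,
            "rejection_rate": float((pvals < alpha).mean())}


def site_detection(n_seeds: int = 20, n_codons: int = 500,
                   omega2: float = 8.0, p2: float = 0.1,
                   threshold: float = 0.95, seed: int = 0) -> dict:
    """BEB detection of positively selected sites under model A.

    Returns pooled sensitivity (fraction of truly selected sites
    flagged) and false-discovery proportion at the threshold.
    """
    tree = Tree.from_newick(FOREGROUND_RADIATION_TREE)
    p01 = 1.0 - p2
    params = CodonSimParams(kappa=2.0, omega0=0.2, omega2=omega2,
                            p0=p01 / 2, p1=p01 / 2, n_codons=n_codons)
    fg = list(FOREGROUND_TIPS)
    tp = fn = fp = 0
    per_seed = []
    for rep in range(n_seeds):
        caln, truth = simulate_codon_alignment(tree, params,
                                               foreground_clade=fg,
                                               seed=seed * 7919 + rep)
        fit = fit_codon_model(tree, caln, "modelA", foreground_tips=fg,
                              n_starts=1, seed=rep, codon_freqs="equal")
        post = eb_site_posteriors(fit, tree, caln, method="BEB")
        flagged = set(post.selected_sites(threshold))
        true_sel = set(truth.selected_sites)
        tp += len(flagged & true_sel)
        fn += len(true_sel - flagged)
        fp += len(flagged - true_sel)
        per_seed.append((len(flagged & true_sel), len(flagged)))
    sens = tp / (tp + fn) if tp + fn else float("nan")
    fdp = fp / (tp + fp) if tp + fp else 0.0
    return {"sensitivity": sens, "false_discovery_proportion": fdp,
            "per_seed": per_seed}


def end_to_end_truth_recovery(seed: int = 1,
                              bootstrap_reps: int = 25) -> dict:
    """Run the pipeline on the synthetic scenario and score the truth.

    Checks: (i) a detected duplication placed on the species-tree edge
    at or ancestral to the trait-gain edge, (ii) the alpha clade
    absent from every trait-reversal species and present in every
    trait-bearing core species, (iii) the planted diagnostic sites
    recovered exactly, (iv) the planted two-gene cluster reported with
    the planted intervening count inside the distance threshold.
    """
    sc = generate_scenario(ScenarioConfig(seed=seed))
    config = PipelineConfig(
        anchor_id=sc.anchor_tip, outgroup_species=sc.outgroup_species,
        clade_tips={"alpha": sc.alpha_tips, "beta": sc.beta_tips},
        focal_genes=sc.config.cluster.focal_ids,
        stages=("search", "refine", "reconcile", "asr", "diagnostics",
                "clusters"),
        bootstrap_reps=bootstrap_reps, seed=seed)
    inputs = PipelineInputs(proteins=sc.proteins, cds=sc.cds,
                            species_tree=sc.species_tree, traits=sc.traits,
                            annotations=sc.annotations)
    report = run_all(inputs, config)

    gain = next(n for n in sc.species_tree.preorder()
                if n.label == sc.gain_clade_label)
    ancestral = set()
    node = gain
    while node is not None:
        ancestral.add(node.label)
        node = node.parent
    placements = report.stages["reconcile"]["placements"]
    placement_ok = any(v in ancestral for v in placements.values())

    presence = set(report.stages["reconcile"]["presence"].get("alpha", []))
    reversals_absent = all(sp not in presence
                           for sp in sc.reversal_species)
    bearing = set(sc.core_species) - set(sc.reversal_species)
    bearing_present = all(sp in presence for sp in bearing)

    found = {s["reference_position"]
             for s in report.stages.get("diagnostics", {}).get("sites", [])}
    planted = {s for s, _, _ in sc.codon_truth.diagnostic_sites}
    diagnostics_exact = found == planted

    clus = report.stages.get("clusters", {})
    cluster_ok = (clus.get("within_threshold") is True and
                  clus.get("intervening_genes") ==
                  sc.config.cluster.n_intervening)

    return {"placement_ok": placement_ok,
            "reversals_absent": reversals_absent,
            "bearing_present": bearing_present,
            "diagnostics_exact": diagnostics_exact,
            "cluster_ok": cluster_ok,
            "report": report,
            "scenario": sc}
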