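"""Synthetic data with known truth for every pipeline stage.

The generator emulates the study design the pipeline targets: a
pure-birth species phylogeny carrying a binary pigment trait with one
forced gain and several reversals; a gene family that duplicates into
alpha/beta paralog clades on the stem of the trait-bearing clade, with
the alpha copy lost in every trait-reverted lineage; codon sequences
evolved under a branch-site regime (positive selection restricted to
foreground branches) with clade-diagnostic residues imposed post hoc;
and a genome annotation in which the two focal genes sit within 50 kb
with one intervening locus.

Each sub-simulator draws from its own stream derived from the master
seed, so adding a stage never perturbs earlier outputs.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional

import numpy as np

from .codonmodel import _CodonEigen, equal_codon_frequencies
from .gencode import (CODON_AA, NONSYNONYMOUS, SENSE_CODONS, SINGLE_CHANGE,
                      translate_cds)
from .iocore import (CodonAlignment, GeneAnnotation, Sequence, TraitTable,
                     write_alignment_fasta, write_fasta, write_gff3,
                     write_trait_csv)
from .tree import Node, Tree, TreeError

STATE_A, STATE_B = "anthocyanin", "betalain"


def _substream(seed: int, stage: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([int(seed), stage]))


# ---------------------------------------------------------------------------
# species tree
# ---------------------------------------------------------------------------

def simulate_species_tree(n_species: int, birth_rate: float = 1.0,
                          seed: int = 0, height: Optional[float] = None) -> Tree:
    """Pure-birth (Yule) ultrametric tree with labelled tips and nodes.

    Tips are ``sp01..spNN``; internal nodes get preorder labels
    ``n1..``.  ``height`` rescales the tree to a fixed root-to-tip
    depth (substitution-like units) after simulation.
    """
    if n_species < 2:
        raise ValueError("need at least 2 species")
    if birth_rate <= 0:
        raise ValueError("birth rate must be positive")
    rng = _substream(seed, 0)
    root = Node()
    active = [root.add_child(Node()), root.add_child(Node())]
    birth = {id(active[0]): 0.0, id(active[1]): 0.0}
    t = 0.0
    while len(active) < n_species:
        t += rng.exponential(1.0 / (birth_rate * len(active)))
        node = active.pop(rng.integers(len(active)))
        node.length = t - birth[id(node)]
        a, b = node.add_child(Node()), node.add_child(Node())
        birth[id(a)] = birth[id(b)] = t
        active.extend([a, b])
    t_end = t + rng.exponential(1.0 / (birth_rate * len(active)))
    for tip in active:
        tip.length = t_end - birth[id(tip)]
    width = len(str(n_species))
    for i, tip in enumerate(root.leaves(), 1):
        tip.label = f"sp{i:0{width}d}"
    tree = Tree(root, rooted=True)
    if height is not None:
        depth = _tree_height(tree)
        scale = height / depth
        for n in tree.postorder():
            if n.length is not None:
                n.length *= scale
    for i, n in enumerate(tree.preorder(), 1):
        if not n.is_leaf:
            n.label = f"n{i}"
    return tree


def _tree_height(tree: Tree) -> float:
    h = {id(tree.root): 0.0}
    best = 0.0
    for n in tree.preorder():
        for c in n.children:
            h[id(c)] = h[id(n)] + (c.length or 0.0)
            best = max(best, h[id(c)])
    return best


# ---------------------------------------------------------------------------
# trait history
# ---------------------------------------------------------------------------

def simulate_trait(tree: Tree, trait_rate: float, root_state: str = STATE_A,
                   forced_events: Optional[dict] = None,
                   seed: int = 0) -> tuple[TraitTable, dict]:
    """Forward Mk1 simulation with optional forced gain/reversal edges.

    ``forced_events`` may hold ``gain``: tip-label list naming the
    clade on whose stem the trait switches to betalain, and
    ``reversals``: a list of such clades forced back to anthocyanin.
    Every reversal clade must be nested inside the gain clade (the
    gain precedes all reversals).  Forced edges override the
    stochastic process on that edge; elsewhere states evolve by Mk1
    at ``trait_rate``.
    """
    rng = _substream(seed, 1)
    forced_events = forced_events or {}
    gain_node = None
    reversal_nodes = []
    if "gain" in forced_events and forced_events["gain"]:
        gain_node = tree.mrca(forced_events["gain"])
    for rev in forced_events.get("reversals", []):
        reversal_nodes.append(tree.mrca(rev))
    if reversal_nodes and gain_node is None:
        raise TreeError("reversals require a gain event")
    gain_desc = set()
    if gain_node is not None:
        gain_desc = {id(n) for n in gain_node.postorder()}
        for r in reversal_nodes:
            if id(r) not in gain_desc or r is gain_node:
                raise TreeError(
                    "conflicting forced events: every reversal must be "
                    "strictly inside the gain clade")
    forced = {id(gain_node): STATE_B} if gain_node is not None else {}
    for r in reversal_nodes:
        forced[id(r)] = STATE_A

    states = {id(tree.root): root_state}
    for n in tree.preorder():
        cur = states[id(n)]
        for c in n.children:
            if id(c) in forced:
                states[id(c)] = forced[id(c)]
                continue
            t = c.length or 0.0
            p_diff = (1.0 - np.exp(-2.0 * trait_rate * t)) / 2.0
            if rng.random() < p_diff:
                states[id(c)] = STATE_B if cur == STATE_A else STATE_A
            else:
                states[id(c)] = cur
    node_states = {}
    for n in tree.preorder():
        key = n.label if n.label else f"id{id(n)}"
        node_states[key] = states[id(n)]
    tips = TraitTable({t.label: states[id(t)] for t in tree.tips()})
    return tips, node_states


# ---------------------------------------------------------------------------
# gene family
# ---------------------------------------------------------------------------

@dataclass
class DupEvent:
    """A duplication on the stem edge above MRCA(clade_tips).

    ``copy`` is the gene-copy name that duplicates there; it is
    replaced by the two ``daughters`` below the event.
    """

    clade_tips: list
    copy: str
    daughters: tuple


@dataclass
class LossEvent:
    """Loss of gene copies in terminal species lineages."""

    copies: list
    species: list


@dataclass
class GeneFamilyTruth:
    duplication_labels: list          # gene-tree internal node labels
    duplication_species_edge: dict    # gene label -> species node label
    presence: dict                    # species -> set of copy names
    copy_names: list


def simulate_gene_family(species_tree: Tree,
                         dup_spec: Iterable[DupEvent],
                         loss_spec: Iterable[LossEvent] = (),
                         rate_scale: float = 1.0,
                         seed: int = 0) -> tuple[Tree, GeneFamilyTruth]:
    """Evolve a gene family along the species tree by known events.

    Without duplications and losses the gene tree is isomorphic to the
    species tree.  Gene tips are named ``species@copy``.  Branch
    lengths track the species tree scaled by ``rate_scale``; a
    duplication node splits its stem edge evenly.
    """
    dup_spec = list(dup_spec)
    loss_spec = list(loss_spec)
    sp_tips = set(species_tree.tip_labels())
    dups_at: dict[int, list[DupEvent]] = {}
    for ev in dup_spec:
        missing = set(ev.clade_tips) - sp_tips
        if missing:
            raise TreeError(f"dup clade tips not in species tree: "
                            f"{sorted(missing)}")
        node = species_tree.mrca(ev.clade_tips)
        dups_at.setdefault(id(node), []).append(ev)
    lost: set[tuple[str, str]] = set()
    for ev in loss_spec:
        for sp in ev.species:
            if sp not in sp_tips:
                raise TreeError(f"loss species {sp!r} not in species tree")
            for copy in ev.copies:
                lost.add((copy, sp))

    dup_nodes: list[Node] = []
    dup_edge: dict[int, str] = {}

    def descend(sp_node: Node, copy: str, edge_len: float):
        """Gene subtree for `copy` entering the stem above sp_node."""
        events = [ev for ev in dups_at.get(id(sp_node), []) if ev.copy == copy]
        if len(events) > 1:
            raise TreeError("at most one duplication per copy per edge")
        if events:
            ev = events[0]
            step = edge_len / 2.0
            node = Node(length=step)
            a = descend_body(sp_node, ev.daughters[0], edge_len - step)
            b = descend_body(sp_node, ev.daughters[1], edge_len - step)
            kids = [x for x in (a, b) if x is not None]
            if not kids:
                return None
            if len(kids) == 1:
                kids[0].length = (kids[0].length or 0.0) + step
                return kids[0]
            for x in kids:
                node.add_child(x)
            dup_nodes.append(node)
            dup_edge[id(node)] = sp_node.label
            return node
        return descend_body(sp_node, copy, edge_len)

    def descend_body(sp_node: Node, copy: str, edge_len: float):
        if sp_node.is_leaf:
            if (copy, sp_node.label) in lost:
                return None
            return Node(label=f"{sp_node.label}@{copy}", length=edge_len)
        kids = []
        for c in sp_node.children:
            sub = descend(c, copy, (c.length or 0.0) * rate_scale)
            if sub is not None:
                kids.append(sub)
        if not kids:
            return None
        if len(kids) == 1:
            kids[0].length = (kids[0].length or 0.0) + edge_len
            return kids[0]
        node = Node(length=edge_len)
        for x in kids:
            node.add_child(x)
        return node

    root_copy = "anc"
    # a dup whose clade is the whole species tree acts at the root
    root_gene = descend(species_tree.root, root_copy, 0.0)
    if root_gene is None:
        raise TreeError("loss specification removed the whole family")
    root_gene.length = None
    gene_tree = Tree(root_gene, rooted=len(root_gene.children) == 2)
    for i, n in enumerate(gene_tree.preorder(), 1):
        if not n.is_leaf and n.label is None:
            n.label = f"g{i}"

    presence: dict[str, set] = {sp: set() for sp in species_tree.tip_labels()}
    copy_names = set()
    for tip in gene_tree.tips():
        sp, copy = tip.label.split("@", 1)
        presence[sp].add(copy)
        copy_names.add(copy)
    truth = GeneFamilyTruth(
        duplication_labels=[n.label for n in dup_nodes],
        duplication_species_edge={n.label: dup_edge[id(n)]
                                  for n in dup_nodes},
        presence=presence,
        copy_names=sorted(copy_names))
    return gene_tree, truth


# ---------------------------------------------------------------------------
# codon alignment
# ---------------------------------------------------------------------------

@dataclass
class CodonSimParams:
    """Branch-site generative regime (model A truth)."""

    kappa: float = 2.0
    omega0: float = 0.2
    omega2: float = 5.0
    p0: float = 0.45
    p1: float = 0.45
    n_codons: int = 300

    def __post_init__(self):
        p2 = 1.0 - self.p0 - self.p1
        if min(self.p0, self.p1, p2) < 0:
            raise ValueError("class proportions must be non-negative")
        if self.kappa <= 0 or self.omega0 < 0 or self.omega2 < 1:
            raise ValueError("invalid codon model parameters")

    @property
    def p2(self) -> float:
        return 1.0 - self.p0 - self.p1

    def class_proportions(self) -> np.ndarray:
        tot = self.p0 + self.p1
        return np.array([self.p0, self.p1,
                         self.p2 * self.p0 / tot, self.p2 * self.p1 / tot])


@dataclass
class CodonSimTruth:
    site_classes: np.ndarray          # 0,1,2,3 per codon (classes 0/1/2a/2b)
    selected_sites: list              # 1-based sites with fg omega2
    diagnostic_sites: list            # list of (site, residue_a, residue_b)
    n_purged_convergent: int = 0      # chance diagnostic columns broken up


def simulate_codon_alignment(gene_tree: Tree, params: CodonSimParams,
                             foreground_clade: Optional[Iterable[str]] = None,
                             diagnostic_spec: Iterable[tuple] = (),
                             seed: int = 0,
                             clade_a_tips: Optional[Iterable[str]] = None,
                             clade_b_tips: Optional[Iterable[str]] = None,
                             ) -> tuple[CodonAlignment, CodonSimTruth]:
    """Simulate codons site-class-wise along the gene tree.

    Sites fall into the four model-A classes with the stated
    proportions.  Classes 2a/2b evolve with ``omega2`` on foreground
    edges (all branches within ``foreground_clade``, stem included) and
    with their background omega elsewhere.  ``diagnostic_spec`` entries
    ``(site, residue_a, residue_b)`` overwrite that codon column to be
    invariant per clade (clade A/B tip sets), emulating observed
    diagnostic residues rather than a selection regime; such sites are
    excluded from the selection truth.
    """
    rng = _substream(seed, 2)
    pi = equal_codon_frequencies()
    n = params.n_codons
    props = params.class_proportions()
    classes = rng.choice(4, size=n, p=props)

    fg_ids = frozenset()
    if foreground_clade:
        mrca = gene_tree.mrca(foreground_clade)
        fg_ids = frozenset(id(x) for x in mrca.postorder())

    # per (class, edge-type) omega; branch lengths are expected
    # substitutions per codon averaged over classes (background rates)
    omega_bg = [params.omega0, 1.0, params.omega0, 1.0]
    omega_fg = [params.omega0, 1.0, params.omega2, params.omega2]
    from .codonmodel import gy94_rate
    rho = float(sum(p * gy94_rate(params.kappa, w, pi)
                    for p, w in zip(props, omega_bg)))
    eigens = {}

    def transition(omega: float, t: float) -> np.ndarray:
        key = round(omega, 12)
        if key not in eigens:
            eigens[key] = _CodonEigen(params.kappa, omega, pi)
        eig = eigens[key]
        return eig.transition(t * eig.mu / rho)

    states = {id(gene_tree.root): rng.choice(len(pi), size=n, p=pi)}
    for node in gene_tree.preorder():
        cur = states[id(node)]
        for c in node.children:
            fg = id(c) in fg_ids
            t = max(c.length or 0.0, 0.0)
            new = np.empty(n, dtype=np.int64)
            for cls in range(4):
                sel = classes == cls
                if not sel.any():
                    continue
                omega = omega_fg[cls] if fg else omega_bg[cls]
                P = transition(omega, t)
                cum = P.cumsum(axis=1)
                u = rng.random(sel.sum())
                rows = cum[cur[sel]]
                new[sel] = (u[:, None] > rows).sum(axis=1)
            states[id(c)] = new

    ids = [t.label for t in gene_tree.tips()]
    codon_rows = {sid: list(states[id(t)])
                  for sid, t in zip(ids, gene_tree.tips())}

    # post-hoc diagnostic residues
    diag = list(diagnostic_spec)
    clade_a = set(clade_a_tips or [])
    clade_b = set(clade_b_tips or [])
    aa_to_codon = {}
    for idx, codon in enumerate(SENSE_CODONS):
        aa_to_codon.setdefault(CODON_AA[codon], idx)
    for site, res_a, res_b in diag:
        if not 1 <= site <= n:
            raise ValueError(f"diagnostic site {site} outside 1..{n}")
        if res_a == res_b:
            raise ValueError("diagnostic residues must differ between clades")
        ca, cb = aa_to_codon[res_a], aa_to_codon[res_b]
        for sid in ids:
            if sid in clade_a:
                codon_rows[sid][site - 1] = ca
            elif sid in clade_b:
                codon_rows[sid][site - 1] = cb

    # the planted sites are the truth: break up columns that drifted
    # into a chance clade-diagnostic contrast, so the emitted data are
    # consistent with the declared diagnostic truth by construction
    n_purged = 0
    if clade_a and clade_b:
        n_purged = _purge_convergent_diagnostics(
            codon_rows, ids, clade_a, clade_b,
            {s for s, _, _ in diag}, n, rng)

    rows = ["".join(SENSE_CODONS[k] for k in codon_rows[sid]) for sid in ids]
    caln = CodonAlignment(ids, rows)
    diag_sites = {s for s, _, _ in diag}
    selected = [i + 1 for i in range(n)
                if classes[i] >= 2 and (i + 1) not in diag_sites]
    truth = CodonSimTruth(site_classes=classes, selected_sites=selected,
                          diagnostic_sites=diag,
                          n_purged_convergent=n_purged)
    return caln, truth


def _purge_convergent_diagnostics(codon_rows: dict, ids: list,
                                  clade_a: set, clade_b: set,
                                  planted: set, n: int,
                                  rng: np.random.Generator,
                                  tau: float = 0.1) -> int:
    """Destroy chance clade-diagnostic columns outside the planted set.

    A column counts as a chance contrast when clade A is invariant for
    a residue absent from clade B whose majority residue frequency is
    >= 1 - tau (the tolerant detection rule).  One clade-A row gets a
    single-nucleotide nonsynonymous substitution there, which removes
    the invariance without touching any other column.
    """
    a_ids = sorted(set(ids) & set(clade_a))
    b_ids = sorted(set(ids) & set(clade_b))
    if not a_ids or not b_ids:
        return 0
    purged = 0
    for _ in range(10):
        changed = False
        for site in range(1, n + 1):
            if site in planted:
                continue
            a_res = {CODON_AA[SENSE_CODONS[codon_rows[s][site - 1]]]
                     for s in a_ids}
            if len(a_res) != 1:
                continue
            ra = next(iter(a_res))
            b_res = [CODON_AA[SENSE_CODONS[codon_rows[s][site - 1]]]
                     for s in b_ids]
            if ra in b_res:
                continue
            top = max(b_res.count(r) for r in set(b_res))
            if top / len(b_res) < 1 - tau:
                continue
            victim = a_ids[rng.integers(len(a_ids))]
            k = codon_rows[victim][site - 1]
            neigh = [j for j in range(len(SENSE_CODONS))
                     if SINGLE_CHANGE[k, j] and NONSYNONYMOUS[k, j]]
            codon_rows[victim][site - 1] = int(neigh[rng.integers(len(neigh))])
            purged += 1
            changed = True
        if not changed:
            break
    return purged


# ---------------------------------------------------------------------------
# genome annotation
# ---------------------------------------------------------------------------

@dataclass
class ClusterSpec:
    chromosome: str = "chr2"
    focal_ids: tuple = ("DODA_alpha", "CYP76AD1_alpha")
    distance: int = 30000          # bp between nearest focal gene ends
    n_intervening: int = 1
    gene_length: int = 1500
    offset: int = 100000           # genomic start of the first focal gene


def make_cluster_annotation(spec: ClusterSpec,
                            extra_genes: int = 3) -> list[GeneAnnotation]:
    """Annotations embedding the focal pair with intervening loci.

    The two focal genes end up exactly ``spec.distance`` bp apart
    (nearest ends) with ``n_intervening`` gene features strictly
    between them; ``extra_genes`` unrelated loci are added around and
    on another chromosome so cluster detection has negatives.
    """
    L = spec.gene_length
    need = spec.n_intervening * (L + 2)
    if spec.distance <= need:
        raise ValueError(
            f"cannot pack {spec.n_intervening} genes of length {L} into "
            f"{spec.distance} bp")
    out = []
    a_start = spec.offset
    a_end = a_start + L - 1
    b_start = a_end + spec.distance + 1
    b_end = b_start + L - 1
    out.append(GeneAnnotation(spec.focal_ids[0], spec.chromosome,
                              a_start, a_end, "+"))
    gap_per = spec.distance // (spec.n_intervening + 1)
    for i in range(spec.n_intervening):
        s = a_end + (i + 1) * gap_per - L // 2
        out.append(GeneAnnotation(f"intervening_{i + 1}", spec.chromosome,
                                  s, s + L - 1, "-"))
    out.append(GeneAnnotation(spec.focal_ids[1], spec.chromosome,
                              b_start, b_end, "+"))
    pos = b_end + 200000
    for i in range(extra_genes):
        chrom = spec.chromosome if i % 2 == 0 else "chr9"
        out.append(GeneAnnotation(f"unrelated_{i + 1}", chrom,
                                  pos, pos + L - 1, "+"))
        pos += 150000
    return sorted(out, key=lambda g: (g.chromosome, g.start))


# ---------------------------------------------------------------------------
# full scenario
# ---------------------------------------------------------------------------

@dataclass
class ScenarioConfig:
    """Study conditions for the end-to-end synthetic scenario."""

    seed: int
    n_species: int = 40
    birth_rate: float = 1.0
    tree_height: float = 1.0        # species-tree depth (trait time units)
    gene_rate_scale: float = 1.0    # substitutions/codon site per time unit
    trait_rate: float = 0.0         # background noise beyond forced events
    n_reversals: int = 3
    codon: CodonSimParams = field(default_factory=CodonSimParams)
    diagnostic_residues: tuple = (("P", "N"), ("W", "A"))
    cluster: ClusterSpec = field(default_factory=ClusterSpec)


@dataclass
class Scenario:
    """Generated data plus complete ground truth."""

    config: ScenarioConfig
    species_tree: Tree
    traits: TraitTable
    node_states: dict
    gene_tree: Tree
    family_truth: GeneFamilyTruth
    codon_alignment: CodonAlignment
    codon_truth: CodonSimTruth
    annotations: list
    # named structure
    outgroup_species: list
    core_species: list              # trait-bearing clade C
    reversal_species: list
    gain_clade_label: str           # species node label of MRCA(C)
    alpha_tips: list
    beta_tips: list
    anchor_tip: str
    proteins: list                  # Sequence (translated)
    cds: list                       # Sequence (ungapped CDS)

    @property
    def diagnostic_sites(self) -> list:
        return self.codon_truth.diagnostic_sites


def _pick_core_clade(tree: Tree, ingroup: Node) -> Node:
    """The trait-bearing core clade: the ingroup's larger child.

    Mirrors the study system, where the pigment clade spans most of
    the ingroup and its stem is old, so the paralog clades born on
    that stem are deeply diverged.
    """
    kids = sorted(ingroup.children,
                  key=lambda c: -len(list(c.leaves())))
    big = kids[0]
    if big.is_leaf:
        return ingroup
    return big


def generate_scenario(config: ScenarioConfig) -> Scenario:
    """Simulate the full paper-like scenario with recorded truth."""
    seed = config.seed
    sp_tree = simulate_species_tree(config.n_species, config.birth_rate,
                                    seed=seed, height=config.tree_height)

    # outgroup = smaller side of the root; core clade C inside the ingroup
    a, b = sp_tree.root.children
    na, nb = len(list(a.leaves())), len(list(b.leaves()))
    og_node, ingroup = (a, b) if na <= nb else (b, a)
    outgroup_species = sorted(t.label for t in og_node.leaves())
    core_node = _pick_core_clade(sp_tree, ingroup)
    core_species = sorted(t.label for t in core_node.leaves())
    if len(core_species) < 2 + config.n_reversals:
        raise TreeError("core clade too small; increase n_species")

    # reversal lineages: spread single-species lineages within C
    core_tips = [t.label for t in core_node.leaves()]
    idx = np.linspace(1, len(core_tips) - 1,
                      config.n_reversals).astype(int)
    reversal_species = sorted({core_tips[i] for i in idx})

    traits, node_states = simulate_trait(
        sp_tree, config.trait_rate, root_state=STATE_A,
        forced_events={"gain": core_species,
                       "reversals": [[s] for s in reversal_species]},
        seed=seed)

    # gene family: alpha/beta duplication on the stem of C; one extra
    # duplication inside alpha; alpha lost in every reversal lineage
    sub = None
    for cand in core_node.postorder():
        if cand.is_leaf or cand is core_node:
            continue
        tips_c = {t.label for t in cand.leaves()}
        if 2 <= len(tips_c) and not (tips_c & set(reversal_species)):
            sub = cand
    dups = [DupEvent(core_species, "anc", ("alpha", "beta"))]
    alpha_names = ["alpha"]
    if sub is not None:
        dups.append(DupEvent(sorted(t.label for t in sub.leaves()),
                             "alpha", ("alphaA", "alphaB")))
        alpha_names = ["alpha", "alphaA", "alphaB"]
    losses = [LossEvent(alpha_names, reversal_species)]
    gene_tree, family_truth = simulate_gene_family(
        sp_tree, dups, losses, rate_scale=config.gene_rate_scale, seed=seed)

    alpha_tips = sorted(t for t in gene_tree.tip_labels()
                        if t.split("@", 1)[1] in alpha_names)
    beta_tips = sorted(t for t in gene_tree.tip_labels()
                       if t.split("@", 1)[1] == "beta")
    # anchor: an alpha copy from a non-reversal core species
    anchor_tip = alpha_tips[0]

    n = config.codon.n_codons
    diag_spec = []
    positions = np.linspace(int(n * 0.3), int(n * 0.8),
                            len(config.diagnostic_residues)).astype(int)
    for pos, (ra, rb) in zip(positions, config.diagnostic_residues):
        diag_spec.append((int(pos), ra, rb))
    caln, codon_truth = simulate_codon_alignment(
        gene_tree, config.codon, foreground_clade=alpha_tips,
        diagnostic_spec=diag_spec, seed=seed,
        clade_a_tips=alpha_tips, clade_b_tips=beta_tips)

    cds = caln.to_sequences(kind="cds")
    proteins = [Sequence(s.id, translate_cds(s.residues), kind="protein")
                for s in cds]
    annotations = make_cluster_annotation(config.cluster)
    gain_label = core_node.label

    return Scenario(
        config=config, species_tree=sp_tree, traits=traits,
        node_states=node_states, gene_tree=gene_tree,
        family_truth=family_truth, codon_alignment=caln,
        codon_truth=codon_truth, annotations=annotations,
        outgroup_species=outgroup_species, core_species=core_species,
        reversal_species=reversal_species, gain_clade_label=gain_label,
        alpha_tips=alpha_tips, beta_tips=beta_tips, anchor_tip=anchor_tip,
        proteins=proteins, cds=cds)


def write_scenario(sc: Scenario, outdir) -> dict:
    """Write all scenario files plus truth.json; returns the paths."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "species_tree": outdir / "species.nwk",
        "gene_tree": outdir / "genetree_true.nwk",
        "proteins": outdir / "proteins.fasta",
        "cds": outdir / "cds.fasta",
        "traits": outdir / "traits.csv",
        "gff": outdir / "genes.gff3",
        "truth": outdir / "truth.json",
    }
    sc.species_tree.write(paths["species_tree"])
    sc.gene_tree.write(paths["gene_tree"])
    write_fasta(sc.proteins, paths["proteins"])
    write_fasta(sc.cds, paths["cds"])
    write_trait_csv(sc.traits, paths["traits"])
    write_gff3(sc.annotations, paths["gff"])
    truth = {
        "node_states": sc.node_states,
        "duplications": sc.family_truth.duplication_species_edge,
        "presence": {sp: sorted(c) for sp, c in
                     sc.family_truth.presence.items()},
        "selected_sites": sc.codon_truth.selected_sites,
        "diagnostic_sites": [[s, a, b] for s, a, b in
                             sc.codon_truth.diagnostic_sites],
        "core_species": sc.core_species,
        "reversal_species": sc.reversal_species,
        "outgroup_species": sc.outgroup_species,
        "gain_clade_label": sc.gain_clade_label,
        "alpha_tips": sc.alpha_tips,
        "beta_tips": sc.beta_tips,
        "anchor_tip": sc.anchor_tip,
        "cluster": {"focal_ids": list(sc.config.cluster.focal_ids),
                    "distance": sc.config.cluster.distance,
                    "n_intervening": sc.config.cluster.n_intervening},
    }
    with open(paths["truth"], "w") as fh:
        json.dump(truth, fh, indent=1, sort_keys=True)
    return paths
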