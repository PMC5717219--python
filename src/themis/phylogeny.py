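"""Joint analysis of multiple biopsies: clone merging, tree enumeration and
maximum-likelihood phylogeny selection.

The five-step procedure:

1. analyze each biopsy separately and identify the genotype and prevalence
   of each clone;
2. compute similarities between clones from different biopsies and merge
   similar ones (Jaccard index over aberrant units, threshold configurable);
3. derive ancestry constraints: clone a is an ancestor of clone b when their
   carrier prevalences sum above 1.0 in at least one biopsy while a's always
   exceeds b's where both are present (pigeonhole: the carriers must nest);
   profile containment (a's events all within b's) adds further constraints;
4. enumerate every rooted tree over the merged clones — plus inferred
   intermediate clones where two clones share events absent elsewhere — that
   satisfies the constraints;
5. refit the joint model once per candidate tree, with the clone chain
   indexing tree edges and each edge's emission means using the subtree
   cell-fraction sum in each biopsy, and keep the maximum-likelihood tree.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import networkx as nx
import numpy as np
import pandas as pd

from .config import RunConfig
from .data import SiteData
from .emissions import ModelParams
from .genotypes import enumerate_genotypes, null_genotype_index
from .inference import (
    ClonalDecomposition,
    PrevalenceConfig,
    em_fit,
    initial_cm,
    run_themis,
    segments_from_path,
    viterbi_decode,
)

ROOT = "normal"


# ---------------------------------------------------------------------------
# Clone profiles

@dataclass
class CloneProfile:
    """Genome-wide event profile of one clone.

    ``cna_units`` maps aberrant germline sites (chrom, pos) to their decoded
    (total, alt) genotype; ``snv_sites`` holds carried somatic sites.
    Prevalences are per biopsy index, zero where the clone is absent.
    """

    clone_id: str
    cna_units: dict
    snv_sites: frozenset
    prevalence_by_biopsy: dict          # cell fractions
    event_prevalence_by_biopsy: dict    # carrier prevalences phi

    @property
    def n_events(self) -> int:
        return len(self.cna_units) + len(self.snv_sites)

    def present_in(self, m: int) -> bool:
        return self.event_prevalence_by_biopsy.get(m, 0.0) > 0.0


def profiles_from_decomposition(dec: ClonalDecomposition, biopsy: int) -> list[CloneProfile]:
    """One profile per decoded clone cluster of a single-biopsy run."""
    assign = dec.site_assignments()
    null_label = "AB"
    out = []
    for z in range(dec.n_clones):
        rows = assign[assign["clone"] == z + 1]
        germ = rows[(rows["type"] == "het") & (rows["genotype"] != null_label)]
        som = rows[(rows["type"] == "som") & (rows["alt_copies"] >= 1)]
        units = {(c, int(p)): (int(t), int(a))
                 for c, p, t, a in zip(germ["chrom"], germ["pos"],
                                       germ["total_copies"], germ["alt_copies"])}
        out.append(CloneProfile(
            clone_id=f"b{biopsy + 1}c{z + 1}",
            cna_units=units,
            snv_sites=frozenset((c, int(p)) for c, p in zip(som["chrom"], som["pos"])),
            prevalence_by_biopsy={biopsy: float(dec.prevalence.cell_fractions[0, z])},
            event_prevalence_by_biopsy={biopsy: float(dec.prevalence.levels[0, z])},
        ))
    return out


def clone_similarity(a: CloneProfile, b: CloneProfile) -> float:
    """Jaccard index over aberrant units: identically-genotyped shared CNA
    units plus shared SNVs, over the union of all aberrant units."""
    shared_cna = sum(1 for u, g in a.cna_units.items() if b.cna_units.get(u) == g)
    union_cna = len(set(a.cna_units) | set(b.cna_units))
    shared_snv = len(a.snv_sites & b.snv_sites)
    union_snv = len(a.snv_sites | b.snv_sites)
    denom = union_cna + union_snv
    if denom == 0:
        return 1.0
    return (shared_cna + shared_snv) / denom


def merge_clones(per_biopsy: Sequence[Sequence[CloneProfile]],
                 threshold: float = 0.8) -> list[CloneProfile]:
    """Union-find merge of similar clones from different biopsies."""
    profiles = [p for group in per_biopsy for p in group]
    parent = list(range(len(profiles)))

    def find(i):
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for i, j in itertools.combinations(range(len(profiles)), 2):
        a, b = profiles[i], profiles[j]
        if set(a.prevalence_by_biopsy) & set(b.prevalence_by_biopsy):
            continue  # clones within one biopsy are distinct by construction
        if clone_similarity(a, b) >= threshold:
            parent[find(i)] = find(j)
    groups: dict = {}
    for i in range(len(profiles)):
        groups.setdefault(find(i), []).append(profiles[i])
    merged = []
    for k, members in enumerate(sorted(groups.values(),
                                       key=lambda ms: ms[0].clone_id)):
        units: dict = {}
        snvs: set = set()
        prev: dict = {}
        eprev: dict = {}
        for p in members:
            for u, g in p.cna_units.items():
                units.setdefault(u, g)
            snvs |= p.snv_sites
            prev.update(p.prevalence_by_biopsy)
            eprev.update(p.event_prevalence_by_biopsy)
        merged.append(CloneProfile(
            clone_id=f"c{k + 1}", cna_units=units, snv_sites=frozenset(snvs),
            prevalence_by_biopsy=prev, event_prevalence_by_biopsy=eprev))
    return merged


# ---------------------------------------------------------------------------
# Constraints and intermediates

def infer_ancestry_constraints(clones: Sequence[CloneProfile]) -> set:
    """(ancestor, descendant) pairs from the prevalence-sum rule.

    (a, b) is emitted exactly when the carrier prevalences satisfy
    p_a + p_b > 1 in at least one biopsy and p_a > p_b in every biopsy where
    both clones are present.  A cycle in the implied order signals
    inconsistent inputs.
    """
    out = set()
    for a, b in itertools.permutations(clones, 2):
        biopsies = set(a.event_prevalence_by_biopsy) | set(b.event_prevalence_by_biopsy)
        sum_gt_1 = any(
            a.event_prevalence_by_biopsy.get(m, 0.0)
            + b.event_prevalence_by_biopsy.get(m, 0.0) > 1.0
            for m in biopsies)
        both = [m for m in biopsies if a.present_in(m) and b.present_in(m)]
        dominated = bool(both) and all(
            a.event_prevalence_by_biopsy[m] > b.event_prevalence_by_biopsy[m]
            for m in both)
        if sum_gt_1 and dominated:
            out.add((a.clone_id, b.clone_id))
    g = nx.DiGraph(out)
    if not nx.is_directed_acyclic_graph(g):
        raise ValueError("ancestry constraints form a cycle; inconsistent prevalences")
    return out


def _shared_events(a: CloneProfile, b: CloneProfile):
    units = {u: g for u, g in a.cna_units.items() if b.cna_units.get(u) == g}
    snvs = a.snv_sites & b.snv_sites
    return units, snvs


def _subset_frac(a: CloneProfile, b: CloneProfile) -> float:
    """Fraction of a's events present identically in b."""
    if a.n_events == 0:
        return 0.0
    units, snvs = _shared_events(a, b)
    return (len(units) + len(snvs)) / a.n_events


def containment_constraints(clones: Sequence[CloneProfile],
                            frac: float = 0.8, min_events: int = 3) -> set:
    """(a, b) when nearly all of a's events recur identically in b's larger
    profile: b inherited them, so a must be an ancestor of b."""
    out = set()
    for a, b in itertools.permutations(clones, 2):
        if a.n_events >= min_events and b.n_events > a.n_events:
            if _subset_frac(a, b) >= frac and _subset_frac(b, a) < frac:
                out.add((a.clone_id, b.clone_id))
    return out


def detect_intermediates(clones: Sequence[CloneProfile], min_shared: int = 5,
                         frac: float = 0.8) -> tuple[list[CloneProfile], set]:
    """Unsampled intermediate clones implied by shared-event splits.

    When two clones share a substantial event set that is neither (almost)
    all of either profile nor (almost) equal to an existing clone's profile,
    an intermediate node carrying exactly the shared events is added, with
    constraints placing it above both sharers.  Intermediates have zero cell
    fraction everywhere (they were never directly observed).
    """
    new: list[CloneProfile] = []
    constraints: set = set()
    seen: set = set()
    for a, b in itertools.combinations(sorted(clones, key=lambda c: c.clone_id), 2):
        units, snvs = _shared_events(a, b)
        n_shared = len(units) + len(snvs)
        if n_shared < min_shared:
            continue
        if _subset_frac(a, b) >= frac or _subset_frac(b, a) >= frac:
            continue  # containment, not a split
        key = (frozenset(units.items()), frozenset(snvs))
        if key in seen:
            continue
        inter = CloneProfile(
            clone_id=f"anc_{a.clone_id}_{b.clone_id}",
            cna_units=dict(units), snv_sites=frozenset(snvs),
            prevalence_by_biopsy={}, event_prevalence_by_biopsy={})
        if any(_subset_frac(inter, c) >= frac and _subset_frac(c, inter) >= frac
               for c in clones):
            continue  # an existing clone already is the shared profile
        seen.add(key)
        new.append(inter)
        constraints.add((inter.clone_id, a.clone_id))
        constraints.add((inter.clone_id, b.clone_id))
        for c in clones:
            if c.n_events >= 3 and _subset_frac(c, inter) >= frac \
                    and inter.n_events > c.n_events:
                constraints.add((c.clone_id, inter.clone_id))
    return new, constraints


# ---------------------------------------------------------------------------
# Trees

@dataclass
class PhylogenyTree:
    """Rooted clone tree with per-biopsy prevalences and edge mutations."""

    parent: dict                      # node id -> parent id; root is "normal"
    prevalences: dict = field(default_factory=dict)   # node -> {biopsy: cell fraction}
    edge_mutations: dict = field(default_factory=dict)  # node -> {"cna_units", "snvs"}
    loglik: Optional[float] = None

    @property
    def nodes(self) -> list:
        return sorted(self.parent)

    def children(self, node: str) -> list:
        return sorted(n for n, p in self.parent.items() if p == node)

    def ancestors(self, node: str) -> list:
        out = []
        while self.parent[node] != ROOT:
            node = self.parent[node]
            out.append(node)
        return out

    def is_ancestor(self, a: str, b: str) -> bool:
        return a in self.ancestors(b)

    def subtree(self, node: str) -> list:
        out, stack = [], [node]
        while stack:
            n = stack.pop()
            out.append(n)
            stack.extend(self.children(n))
        return sorted(out)

    def effective_prevalence(self, node: str, m: int) -> float:
        """Carrier prevalence of events on this node's edge in biopsy m:
        cell-fraction sum over the subtree below the edge."""
        return float(sum(self.prevalences.get(n, {}).get(m, 0.0)
                         for n in self.subtree(node)))

    def to_newick(self, with_prevalences: bool = True) -> str:
        def fmt(node: str) -> str:
            kids = self.children(node)
            label = node
            if with_prevalences and node != ROOT and node in self.prevalences:
                pv = self.prevalences[node]
                vals = "|".join(f"{pv.get(m, 0.0):.2f}" for m in sorted(pv) or [0])
                label = f"{node}[&cell_fraction={vals}]" if pv else node
            if not kids:
                return label
            return "(" + ",".join(fmt(k) for k in kids) + ")" + label

        return fmt(ROOT) + ";"


def enumerate_phylogenies(clones: Sequence[CloneProfile],
                          constraints: set) -> list[PhylogenyTree]:
    """All rooted trees over the clones satisfying every (ancestor, descendant)
    constraint, in deterministic order.

    Each clone picks a parent among the root and the other clones; the
    assignment must form a tree (acyclic) and respect every constraint as a
    strict ancestor relationship.  The constraint graph must be acyclic.
    """
    ids = sorted(c.clone_id for c in clones)
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate clone ids")
    cg = nx.DiGraph()
    cg.add_nodes_from(ids)
    cg.add_edges_from(constraints)
    if not nx.is_directed_acyclic_graph(cg):
        raise ValueError("constraint set contains a cycle")
    if len(ids) > 8:
        raise ValueError(f"{len(ids)} clones: enumeration over parent maps is "
                         "intractable; prune with constraints first")
    out = []
    choices = [[ROOT] + [o for o in ids if o != c] for c in ids]
    for combo in itertools.product(*choices):
        parent = dict(zip(ids, combo))
        g = nx.DiGraph((p, c) for c, p in parent.items())
        g.add_node(ROOT)
        if not nx.is_arborescence(g):
            continue
        tree = PhylogenyTree(parent=parent)
        if all(tree.is_ancestor(a, b) for a, b in constraints):
            out.append(tree)
    if not out:
        warnings.warn("no phylogeny satisfies the constraint set")
    return out


# ---------------------------------------------------------------------------
# Tree-encoded joint model

def tree_loglik(
    tree: PhylogenyTree,
    sites: SiteData,
    config: Optional[RunConfig] = None,
    init_params: Optional[ModelParams] = None,
) -> tuple[float, ClonalDecomposition]:
    """Likelihood of the joint multi-biopsy model encoded by a candidate tree.

    The clone chain indexes tree edges (one state per non-root node); the
    emission mean for biopsy m of an event on edge z uses the subtree
    cell-fraction sum below z, so a mutation is carried by its originating
    clone and all descendants.  Variances and priors are retrained by EM;
    prevalences are fixed by the tree.
    """
    cfg = config or RunConfig()
    nodes = tree.nodes
    M = sites.n_biopsies
    levels = np.array([[tree.effective_prevalence(n, m) for n in nodes]
                       for m in range(M)])
    if np.any(levels > 1.0 + 1e-9):
        raise ValueError("subtree prevalence sums exceed 1; invalid tree")
    prev = PrevalenceConfig(levels=np.clip(levels, 0.0, 1.0), ordered=False)
    genotypes = enumerate_genotypes(cfg.c_max)
    if init_params is None:
        offsets = (np.asarray(cfg.offsets, float) if cfg.offsets is not None
                   else initial_cm(sites))
        init_params = ModelParams.initial(
            M, len(genotypes), len(nodes),
            n_levels=cfg.n_prevalence_levels, offsets=offsets,
            min_effect=cfg.min_effect)
    params, trace = em_fit(
        sites, init_params, prev, genotypes=genotypes,
        max_iter=cfg.joint_max_iter, tol=cfg.tol,
        estimate_transitions=cfg.estimate_transitions)
    path = viterbi_decode(sites, params, prev, genotypes)
    dec = ClonalDecomposition(
        path=path, prevalence=prev, segments=segments_from_path(sites, path, genotypes),
        params=params, loglik=trace[-1], chain_loglik=trace[-1],
        genotypes=genotypes, trace=trace, config=cfg, sites=sites)
    return float(trace[-1]), dec


def _edge_mutations(tree: PhylogenyTree, dec: ClonalDecomposition) -> dict:
    """Newly acquired events per edge from the joint decoded path."""
    nodes = tree.nodes
    assign = dec.site_assignments()
    null_idx = null_genotype_index(dec.genotypes)
    out = {}
    for z, node in enumerate(nodes):
        rows = assign[assign["clone"] == z + 1]
        germ = rows[(rows["type"] == "het") & (rows["genotype"] != "AB")]
        som = rows[(rows["type"] == "som") & (rows["alt_copies"] >= 1)]
        out[node] = {
            "cna_units": {(c, int(p)): (int(t), int(a))
                          for c, p, t, a in zip(germ["chrom"], germ["pos"],
                                                germ["total_copies"],
                                                germ["alt_copies"])},
            "snvs": frozenset((c, int(p)) for c, p in zip(som["chrom"], som["pos"])),
        }
    return out


def edge_mutation_table(tree: PhylogenyTree) -> pd.DataFrame:
    """Per-edge counts: germline-het sites affected by new CNAs, and new SNVs."""
    rows = []
    for node in tree.nodes:
        muts = tree.edge_mutations.get(node, {"cna_units": {}, "snvs": frozenset()})
        rows.append({
            "edge": f"{tree.parent[node]}->{node}",
            "n_het_sites_cna": len(muts["cna_units"]),
            "n_snvs": len(muts["snvs"]),
        })
    return pd.DataFrame(rows)


def select_phylogeny(
    candidates: Sequence[PhylogenyTree],
    sites: SiteData,
    config: Optional[RunConfig] = None,
) -> tuple[PhylogenyTree, list]:
    """Refit the joint model for every candidate and keep the ML tree.

    Returns (best tree with loglik and edge mutations attached, ranking of
    (tree, loglik) pairs in score order).
    """
    if not candidates:
        raise ValueError("no candidate phylogenies to score")
    cfg = config or RunConfig()
    scored, decs = [], {}
    for i, tree in enumerate(candidates):
        try:
            ll, dec = tree_loglik(tree, sites, cfg)
        except ValueError:
            continue
        tree.loglik = ll
        scored.append((tree, ll))
        decs[id(tree)] = dec
    if not scored:
        raise ValueError("every candidate tree was infeasible")
    scored.sort(key=lambda t: -t[1])
    best = scored[0][0]
    best.edge_mutations = _edge_mutations(best, decs[id(best)])
    best._decomposition = decs[id(best)]
    return best, scored


# ---------------------------------------------------------------------------
# Five-step driver

@dataclass
class JointResult:
    per_biopsy: list                  # ClonalDecomposition per biopsy
    clones: list                      # merged CloneProfile list (+ intermediates)
    constraints: set
    candidates: list                  # (tree, loglik) ranking
    tree: PhylogenyTree
    decomposition: Optional[ClonalDecomposition] = None


def joint_analysis(sites: SiteData, config: Optional[RunConfig] = None) -> JointResult:
    """Run the five-step multi-biopsy procedure on a shared-site table."""
    cfg = config or RunConfig()
    if sites.n_biopsies < 2:
        raise ValueError("joint analysis needs at least two biopsies")
    per_biopsy, per_profiles = [], []
    for m in range(sites.n_biopsies):
        dec = run_themis(sites.select_biopsy(m), cfg)
        per_biopsy.append(dec)
        per_profiles.append(profiles_from_decomposition(dec, m))
        gaps = -np.diff(dec.prevalence.levels[0])
        step = 1.0 / cfg.n_prevalence_levels
        if dec.n_clones > 1 and np.any(gaps < 2 * step - 1e-9):
            warnings.warn(
                f"biopsy {m + 1}: clone prevalences within two grid steps; "
                "clones may not be reliably discernible")
    clones = merge_clones(per_profiles, threshold=cfg.merge_threshold)
    constraints = infer_ancestry_constraints(clones)
    constraints |= containment_constraints(clones, frac=cfg.merge_threshold)
    inter, extra = detect_intermediates(clones, min_shared=cfg.min_shared_events,
                                        frac=cfg.merge_threshold)
    clones = clones + inter
    constraints |= extra
    candidates = enumerate_phylogenies(clones, constraints)
    cell_frac = {c.clone_id: dict(c.prevalence_by_biopsy) for c in clones}
    for tree in candidates:
        tree.prevalences = cell_frac
    best, ranking = select_phylogeny(candidates, sites, cfg)
    return JointResult(per_biopsy=per_biopsy, clones=clones,
                       constraints=constraints, candidates=ranking,
                       tree=best, decomposition=getattr(best, "_decomposition", None))
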