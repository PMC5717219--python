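"""Synthetic multi-biopsy patients with known clonal truth.

The generator runs the observation model forward: a clone tree with per-edge
CNA segments and SNV sites is laid over a synthetic genome of germline
heterozygous and somatic sites; each event's carrier prevalence in a biopsy
is the cell-fraction sum over the subtree below its edge (an event is
carried by the clone it arose in and all descendants); allelic ratios and
log depth ratios are drawn from the Gaussian observation model around the
deterministic expected signals, with allelic ratios clipped to [0, 1].

Default study conditions: three chromosomes with inter-site distances drawn
log-uniformly between 10^2 and 10^5 bp, a few thousand germline-het sites
plus on the order of 1% somatic-SNV sites, events arranged so that only one
clone's event covers any given position, and a nonzero log-ratio offset so
the two-pass offset calibration is exercised.  Everything is seed
deterministic.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

from .data import SiteData
from .genotypes import NORMAL_TOTAL

ROOT = "normal"

#: genotype cycle used when laying out CNA blocks; every clone gets at least
#: one 1-copy (LOH) event so single-cell region classes are populated.
#: single-alternative-copy gains (alt_copies == 1, e.g. AAB) are excluded:
#: their germline signals depend only on (total-2)*prevalence, making them a
#: mutually aliased, prevalence-unidentifiable family — study conditions use
#: identifiable event genotypes instead
_GENOTYPE_CYCLE = [(1, 0), (3, 2), (1, 1), (2, 0), (4, 2), (2, 2), (4, 3), (1, 0)]


@dataclass(frozen=True)
class CNAEvent:
    chrom: str
    start: int       # 1-based closed genomic bounds
    end: int
    total_copies: int
    alt_copies: int


@dataclass
class CloneSpec:
    name: str
    parent: str                       # another clone name, or "normal"
    cnas: list = field(default_factory=list)        # CNAEvent
    snvs: list = field(default_factory=list)        # (chrom, pos)


@dataclass
class TruthSpec:
    """Complete description of a synthetic patient."""

    chroms: list                      # chromosome names in order
    positions: dict                   # chrom -> int array of site positions
    site_types: dict                  # chrom -> 0/1 array (het/som)
    clones: list                      # CloneSpec, parents forming a tree
    biopsies: list                    # per biopsy: {clone name: cell fraction}
    sigma_A: tuple = (0.05, 0.05)     # per site type (het, som)
    sigma_L: float = 0.2
    offsets: tuple = (0.25,)          # c_m per biopsy
    seed: int = 0

    def __post_init__(self) -> None:
        names = [c.name for c in self.clones]
        if len(set(names)) != len(names):
            raise ValueError("duplicate clone names")
        known = set(names) | {ROOT}
        for c in self.clones:
            if c.parent not in known or c.parent == c.name:
                raise ValueError(f"clone {c.name} has invalid parent {c.parent}")
        if len(self.biopsies) != len(self.offsets):
            raise ValueError("need one log-ratio offset per biopsy")
        for prev in self.biopsies:
            total = sum(prev.values())
            if total > 1.0 + 1e-9:
                raise ValueError(f"tumor cell fractions sum to {total} > 1 in a biopsy")
            if set(prev) - set(names):
                raise ValueError("biopsy references unknown clones")

    @property
    def n_biopsies(self) -> int:
        return len(self.biopsies)

    def subtree_prevalence(self, clone: str, biopsy: int) -> float:
        """Carrier prevalence of events on ``clone``'s edge: cell-fraction sum
        over the clone and all its descendants in the biopsy."""
        children: dict = {}
        for c in self.clones:
            children.setdefault(c.parent, []).append(c.name)
        total, stack = 0.0, [clone]
        while stack:
            node = stack.pop()
            total += self.biopsies[biopsy].get(node, 0.0)
            stack.extend(children.get(node, []))
        return total

    def to_yaml(self, path) -> None:
        d = {
            "chroms": list(self.chroms),
            "positions": {c: np.asarray(p).tolist() for c, p in self.positions.items()},
            "site_types": {c: np.asarray(t).tolist() for c, t in self.site_types.items()},
            "clones": [
                {"name": c.name, "parent": c.parent,
                 "cnas": [{"chrom": e.chrom, "start": int(e.start), "end": int(e.end),
                           "total_copies": int(e.total_copies),
                           "alt_copies": int(e.alt_copies)} for e in c.cnas],
                 "snvs": [[s[0], int(s[1])] for s in c.snvs]}
                for c in self.clones
            ],
            "biopsies": [dict(b) for b in self.biopsies],
            "sigma_A": list(self.sigma_A), "sigma_L": float(self.sigma_L),
            "offsets": list(self.offsets), "seed": int(self.seed),
        }
        with open(path, "w") as fh:
            yaml.safe_dump(d, fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "TruthSpec":
        with open(path) as fh:
            d = yaml.safe_load(fh)
        clones = [
            CloneSpec(
                name=c["name"], parent=c["parent"],
                cnas=[CNAEvent(**e) for e in c["cnas"]],
                snvs=[(s[0], int(s[1])) for s in c["snvs"]],
            )
            for c in d["clones"]
        ]
        return cls(
            chroms=d["chroms"],
            positions={c: np.asarray(p, dtype=np.int64) for c, p in d["positions"].items()},
            site_types={c: np.asarray(t, dtype=np.int8) for c, t in d["site_types"].items()},
            clones=clones, biopsies=d["biopsies"],
            sigma_A=tuple(d["sigma_A"]), sigma_L=float(d["sigma_L"]),
            offsets=tuple(d["offsets"]), seed=int(d["seed"]),
        )


# ---------------------------------------------------------------------------
# Forward simulation

def simulate_patient(spec: TruthSpec) -> tuple[SiteData, pd.DataFrame]:
    """Draw observations for every biopsy; returns (site data, truth table).

    The truth table has one row per site with the generating clone (empty for
    unmutated sites), the event genotype, and per-biopsy carrier prevalence
    ``phi_m`` and clonality status ``status_m`` (normal / clonal / subclonal;
    an event whose carrier prevalence equals the biopsy's total tumor
    fraction is clonal there, an absent event reads as normal).
    """
    rng = np.random.default_rng(spec.seed)
    M = spec.n_biopsies
    chrom_col, pos_col, type_col = [], [], []
    clone_col, tot_col, alt_col = [], [], []
    clone_names = [c.name for c in spec.clones]
    clone_of = {}
    for c in spec.clones:
        for chrom, pos in c.snvs:
            clone_of[(chrom, int(pos))] = c.name

    for chrom in spec.chroms:
        pos = np.asarray(spec.positions[chrom], dtype=np.int64)
        stype = np.asarray(spec.site_types[chrom], dtype=np.int8)
        T = len(pos)
        owner = np.full(T, "", dtype=object)
        tot = np.full(T, NORMAL_TOTAL, dtype=np.int64)
        alt = np.ones(T, dtype=np.int64)
        for c in spec.clones:
            for ev in c.cnas:
                if ev.chrom != chrom:
                    continue
                mask = (pos >= ev.start) & (pos <= ev.end)
                clash = mask & (owner != "") & (owner != c.name)
                if clash.any():
                    raise ValueError(
                        f"overlapping events from different clones on {chrom} "
                        f"near {pos[clash][0]} (one event per position)")
                owner[mask] = c.name
                tot[mask] = ev.total_copies
                alt[mask] = ev.alt_copies
        for t in np.where(stype == 1)[0]:
            key = (chrom, int(pos[t]))
            cl = clone_of.get(key)
            if cl is None:
                raise ValueError(f"somatic site {key} is not assigned to a clone")
            if owner[t] not in ("", cl):
                raise ValueError(f"somatic site {key} falls in another clone's CNA")
            if owner[t] == "":
                owner[t] = cl       # SNV on a diploid background: genotype AB
                tot[t], alt[t] = 2, 1
            elif alt[t] < 1:
                raise ValueError(f"somatic site {key} inside an alt-free CNA")
        chrom_col.append(np.full(T, chrom, dtype=object))
        pos_col.append(pos)
        type_col.append(stype)
        clone_col.append(owner)
        tot_col.append(tot)
        alt_col.append(alt)

    chrom_all = np.concatenate(chrom_col)
    pos_all = np.concatenate(pos_col)
    type_all = np.concatenate(type_col)
    clone_all = np.concatenate(clone_col)
    tot_all = np.concatenate(tot_col)
    alt_all = np.concatenate(alt_col)
    T = len(pos_all)

    phi = np.zeros((M, T))
    for m in range(M):
        by_clone = {name: spec.subtree_prevalence(name, m) for name in clone_names}
        phi[m] = np.array([by_clone.get(cl, 0.0) if cl else 0.0 for cl in clone_all])

    A = np.empty((M, T))
    L = np.empty((M, T))
    sA = np.asarray(spec.sigma_A, dtype=float)
    truth_cols: dict = {}
    for m in range(M):
        # sites with phi = 0 (event absent or no event) fall back to normal signal
        eff_tot = np.where(phi[m] > 0, tot_all, NORMAL_TOTAL)
        eff_alt = np.where(phi[m] > 0, alt_all, 1)
        mu_a = np.empty(T)
        for d in (0, 1):
            mask = type_all == d
            mu_a[mask] = _diag_allelic(eff_tot[mask], eff_alt[mask], phi[m][mask], d)
        mu_l = _diag_logratio(eff_tot, phi[m], spec.offsets[m])
        A[m] = np.clip(rng.normal(mu_a, sA[type_all]), 0.0, 1.0)
        L[m] = rng.normal(mu_l, spec.sigma_L)
        tumor_total = sum(spec.biopsies[m].values())
        status = np.where(
            phi[m] <= 0, "normal",
            np.where(np.abs(phi[m] - tumor_total) < 1e-9, "clonal", "subclonal"))
        truth_cols[f"phi_{m + 1}"] = phi[m]
        truth_cols[f"status_{m + 1}"] = status

    sites = SiteData(chrom_all, pos_all, type_all, A, L)
    truth = pd.DataFrame({
        "chrom": chrom_all, "pos": pos_all,
        "type": np.where(type_all == 1, "som", "het"),
        "clone": clone_all,
        "total_copies": tot_all, "alt_copies": alt_all,
        **truth_cols,
    })
    return sites, truth


def _diag_allelic(tot, alt, phi, site_type):
    n_alt_normal = 1 if site_type == 0 else 0
    denom = tot * phi + NORMAL_TOTAL * (1.0 - phi)
    numer = alt * phi + n_alt_normal * (1.0 - phi)
    return np.where(denom > 0, numer / np.where(denom > 0, denom, 1.0), 0.5)


def _diag_logratio(tot, phi, c_m):
    eff = np.maximum(tot * phi + NORMAL_TOTAL * (1.0 - phi), 0.01)
    return np.log2(eff / NORMAL_TOTAL) + c_m


# ---------------------------------------------------------------------------
# Genome / layout factories

def _chrom_layout(rng, n_sites, n_som, n_event_blocks, event_frac, clones_cycle,
                  genotype_offset):
    """Partition a chromosome's site indices into alternating neutral and
    event blocks; returns (event assignments, somatic indices)."""
    gaps = np.exp(rng.uniform(np.log(1e2), np.log(1e5), size=n_sites)).astype(np.int64)
    gaps = np.maximum(gaps, 1)
    positions = np.cumsum(gaps)
    n_clones = len(clones_cycle)
    ev_len = max(int(event_frac * n_sites / n_event_blocks), 3)
    gap_len = max(int((1.0 - event_frac) * n_sites / (n_event_blocks + 1)), 2)
    events = []           # (start_idx, end_idx, clone, (tot, alt))
    i = gap_len
    b = 0
    while b < n_event_blocks and i + ev_len < n_sites - 2:
        clone = clones_cycle[b % n_clones]
        geno = _GENOTYPE_CYCLE[(b + genotype_offset) % len(_GENOTYPE_CYCLE)]
        events.append((i, i + ev_len - 1, clone, geno))
        i += ev_len + gap_len
        b += 1
    in_event = np.zeros(n_sites, dtype=bool)
    for s, e, _, _ in events:
        in_event[s : e + 1] = True
    neutral = np.where(~in_event)[0]
    som_idx = np.sort(rng.choice(neutral, size=min(n_som, len(neutral)), replace=False))
    return positions, events, som_idx


def _build_spec(seed, clones_chain, biopsies, het_per_chrom, som_per_chrom,
                n_chrom, sigma_A, sigma_L, offsets, event_blocks, event_frac):
    rng = np.random.default_rng(seed)
    clone_names = [name for name, _ in clones_chain]
    chroms = [f"chr{i + 1}" for i in range(n_chrom)]
    positions, site_types = {}, {}
    cnas = {name: [] for name in clone_names}
    snvs = {name: [] for name in clone_names}
    snv_rr = 0
    for ci, chrom in enumerate(chroms):
        n_total = het_per_chrom + som_per_chrom
        pos, events, som_idx = _chrom_layout(
            rng, n_total, som_per_chrom, event_blocks, event_frac,
            clone_names, genotype_offset=ci)
        stype = np.zeros(n_total, dtype=np.int8)
        stype[som_idx] = 1
        # somatic sites must not sit inside an event block of another clone
        positions[chrom] = pos
        site_types[chrom] = stype
        for s, e, clone, (tot, alt) in events:
            # trim CNA bounds so no somatic site is swallowed accidentally
            cnas[clone].append(CNAEvent(chrom, int(pos[s]), int(pos[e]), tot, alt))
        for t in som_idx:
            clone = clone_names[snv_rr % len(clone_names)]
            snv_rr += 1
            snvs[clone].append((chrom, int(pos[t])))
    clone_specs = [
        CloneSpec(name=name, parent=parent, cnas=cnas[name], snvs=snvs[name])
        for name, parent in clones_chain
    ]
    return TruthSpec(
        chroms=chroms, positions=positions, site_types=site_types,
        clones=clone_specs, biopsies=biopsies,
        sigma_A=sigma_A, sigma_L=sigma_L, offsets=offsets,
        seed=int(rng.integers(2**31 - 1)),
    )


def two_clone_spec(seed=0, het_per_chrom=3300, som_per_chrom=34, n_chrom=3,
                   prevalences=(0.40, 0.35), sigma_A=(0.05, 0.05), sigma_L=0.2,
                   offset=0.25, event_blocks=10, event_frac=0.35) -> TruthSpec:
    """A parent/child chain patient: the parent clone's events are carried by
    parent + child cells (default cell fractions 0.40 and 0.35, so carrier
    prevalences 0.75 and 0.35)."""
    chain = [("clone1", ROOT), ("clone2", "clone1")]
    biopsy = {"clone1": prevalences[0], "clone2": prevalences[1]}
    return _build_spec(seed, chain, [biopsy], het_per_chrom, som_per_chrom,
                       n_chrom, sigma_A, sigma_L, (offset,), event_blocks, event_frac)


def three_clone_spec(seed=0, het_per_chrom=1100, som_per_chrom=12, n_chrom=6,
                     prevalences=(0.45, 0.30, 0.20), sigma_A=(0.05, 0.05),
                     sigma_L=0.2, offset=0.25, event_blocks=9,
                     event_frac=0.35) -> TruthSpec:
    """A three-clone chain (carrier prevalences 0.95 / 0.50 / 0.20 by default).

    The carrier levels deliberately avoid exact 2:1 ratios: genotype (n, a)
    carried at prevalence 2p is indistinguishable at germline sites from
    (2n-2, 2a-1) at p, so a composition sitting exactly on that coincidence
    is unidentifiable in a way real tumors essentially never are.
    """
    chain = [("clone1", ROOT), ("clone2", "clone1"), ("clone3", "clone2")]
    biopsy = {f"clone{i + 1}": p for i, p in enumerate(prevalences)}
    return _build_spec(seed, chain, [biopsy], het_per_chrom, som_per_chrom,
                       n_chrom, sigma_A, sigma_L, (offset,), event_blocks, event_frac)


def multi_biopsy_spec(seed=0, het_per_chrom=400, som_per_chrom=10, n_chrom=3,
                      sigma_A=(0.03, 0.03), sigma_L=0.1,
                      offsets=(0.25, 0.2, 0.3), event_blocks=10,
                      event_frac=0.4) -> TruthSpec:
    """Three biopsies of one patient on a branching tree.

    Clone A is ancestral and present everywhere; B appears only in the first
    biopsy; C and D appear in the second and third biopsies and descend from
    B through an unsampled intermediate CD (cell fraction zero in every
    biopsy), mimicking a metastatic progression series.
    """
    chain = [("A", ROOT), ("B", "A"), ("CD", "B"), ("C", "CD"), ("D", "CD")]
    biopsies = [
        {"A": 0.50, "B": 0.30},
        {"A": 0.45, "C": 0.35},
        {"A": 0.40, "D": 0.40},
    ]
    return _build_spec(seed, chain, biopsies, het_per_chrom, som_per_chrom,
                       n_chrom, sigma_A, sigma_L, offsets, event_blocks, event_frac)


# ---------------------------------------------------------------------------
# Synthetic single cells

def simulate_cells(regions, n_cells=200, class_mix=(0.1, 0.6, 0.3),
                   depth=10000, seed=0):
    """Poisson single-cell coverage over a region set.

    Each cell belongs to normal / parent / child with probabilities
    ``class_mix``; per-segment counts are Poisson with rate proportional to
    segment length times the class's relative copy number (1 everywhere for
    normal cells, 0.5 in clonal-LOH regions for tumor cells, additionally
    0.5 in subclonal-LOH regions for child cells).  ``depth`` is the expected
    total read count per cell.  Returns (cells, true labels).
    """
    from .singlecell import RELATIVE_COPY, CellCoverage, REGION_CLASSES

    rng = np.random.default_rng(seed)
    lens = {rc: np.array([r.length for r in getattr(regions, rc)], dtype=float)
            for rc in REGION_CLASSES}
    total_len = sum(l.sum() for l in lens.values())
    if total_len <= 0:
        raise ValueError("region set has zero total length")
    labels = rng.choice(["normal", "parent", "child"], size=n_cells, p=class_mix)
    cells, truth = [], []
    for i in range(n_cells):
        lab = str(labels[i])
        rel = RELATIVE_COPY[lab]
        counts = {}
        expected_total = sum(lens[rc].sum() * rel[rc] for rc in REGION_CLASSES)
        lam = depth / expected_total
        for rc in REGION_CLASSES:
            counts[rc] = rng.poisson(lam * lens[rc] * rel[rc]).astype(np.int64)
        total = int(sum(c.sum() for c in counts.values()))
        cells.append(CellCoverage(
            cell_id=f"cell{i + 1}", counts=counts, total_reads=total,
            short_read_fraction=float(rng.beta(2.0, 50.0))))
        truth.append(lab)
    return cells, truth


# ---------------------------------------------------------------------------
# Recovery scoring

def score_recovery(decomposition, truth: pd.DataFrame, biopsy: int = 0) -> dict:
    """Error percentages of a decoded decomposition against simulation truth.

    Returns the percentage of sites with the genotype wrong, with the
    clonal/subclonal status wrong, and with either wrong — matching the
    simulation-study metrics.  The "either" rate is at least the maximum of
    the other two by construction.
    """
    assign = decomposition.site_assignments()
    if len(assign) != len(truth):
        raise ValueError("decomposition and truth cover different site sets")
    if not (np.array_equal(assign["pos"].to_numpy(), truth["pos"].to_numpy())
            and np.array_equal(assign["chrom"].to_numpy(), truth["chrom"].to_numpy())):
        raise ValueError("decomposition and truth site coordinates differ")
    phi = truth[f"phi_{biopsy + 1}"].to_numpy()
    true_tot = np.where(phi > 0, truth["total_copies"].to_numpy(), NORMAL_TOTAL)
    true_alt = np.where(phi > 0, truth["alt_copies"].to_numpy(), 1)
    som = truth["type"].to_numpy() == "som"
    # at somatic sites an absent SNV reads as zero alternative copies
    true_alt = np.where(som & (phi <= 0), 0, true_alt)
    dec_tot = assign["total_copies"].to_numpy()
    dec_alt = assign["alt_copies"].to_numpy()
    geno_wrong = (dec_tot != true_tot) | (dec_alt != true_alt)
    # genotype identity at somatic sites is about the SNV: compare alt presence
    geno_wrong = np.where(som, (dec_alt >= 1) != (true_alt >= 1), geno_wrong)
    status_true = truth[f"status_{biopsy + 1}"].to_numpy()
    status_wrong = assign["status"].to_numpy() != status_true
    either = geno_wrong | status_wrong
    T = len(truth)
    return {
        "genotype_error_pct": 100.0 * float(geno_wrong.sum()) / T,
        "clonality_error_pct": 100.0 * float(status_wrong.sum()) / T,
        "either_error_pct": 100.0 * float(either.sum()) / T,
    }
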