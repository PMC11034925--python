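"""Genome-evolution simulator: a multi-species cohort with planted CNEs.

The simulator stands in for a real teleost genome panel. A root genome with
genes and regulatory elements evolves down a fixed species tree under
Jukes-Cantor substitutions; conserved elements mutate at an age-graded
fraction of the neutral rate. Three element age classes are planted at the
nodes where the corresponding real elements arose: "vertebrate" elements in
the root genome, "neopterygian" elements in the gar+teleost ancestor, and
"3R" elements in the teleost ancestor right after a whole-genome
duplication. The WGD duplicates every chromosome and retains duplicated
gene/element loci with a configurable probability; elements can be lost
(whole-span deletion) on any branch; inversions and interspersed repeat
insertions add structural noise. Full ground truth (per-species element
coordinates, loss events, paralogous pairs, true target genes) is recorded.

By default evolution is substitution-only apart from these tracked
structural events, so homologous features stay exactly position-mapped.
"""

from __future__ import annotations

import copy as _copy
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import dendropy
import numpy as np
import pandas as pd

from ._seqtools import decode, encode, revcomp_arr
from .model import GenomeSet, Interval, OrthologyTable, SpeciesGenome, SpeciesTree

log = logging.getLogger(__name__)

DEFAULT_NEWICK = (
    "(cmi:0.9,(hsa:0.8,(loc:0.6,((phy:0.6,(dre:0.5,ame:0.5)nc1b:0.1)nc1:0.25,"
    "(tru:0.5,sau:0.5)nc2:0.25)ntel:0.3)nneop:0.25)nbony:0.25)root;"
)

AGE_CLASSES = ("vertebrate", "neopterygian", "3R")


@dataclass
class SimConfig:
    """Study conditions for one synthetic cohort.

    Branch lengths are expected substitutions per site; rate scales multiply
    the neutral rate inside features. Defaults give a cohort in which the
    two focal pairs (dre/ame and tru/sau) sit at ~1.0 substitutions/site of
    neutral divergence - deep enough that neutral sequence is unalignable
    while planted elements stay comfortably above the 70%-identity window
    threshold.
    """

    seed: int = 42
    newick: str = DEFAULT_NEWICK
    clade1: tuple[str, ...] = ("dre", "ame", "phy")
    clade2: tuple[str, ...] = ("tru", "sau")
    outgroup: tuple[str, ...] = ("loc",)
    vertebrates: tuple[str, ...] = ("hsa", "cmi")
    genome_length: int = 1_200_000
    n_chromosomes: int = 4
    n_genes: int = 40
    n_cne_vertebrate: int = 40
    n_cne_neopterygian: int = 45
    n_cne_3r: int = 75
    cne_length_range: tuple[int, int] = (400, 800)
    #: per-age-class fraction of the neutral substitution rate inside elements
    cne_rate_scales: dict = field(
        default_factory=lambda: {"vertebrate": 0.05, "neopterygian": 0.10, "3R": 0.15}
    )
    exon_rate_scale: float = 0.25
    loss_prob_per_branch: float = 0.02
    wgd_branch: str = "ntel"
    neop_branch: str = "nneop"
    wgd_retention: float = 0.6
    inversion_rate: float = 1.0
    repeat_density: float = 20.0  # copies per Mb inserted on each terminal branch
    repeat_length: int = 400
    repeat_divergence: float = 0.05
    annotated_repeat_fraction: float = 0.7
    #: fraction of gained (neop / 3R) elements planted near novel-target loci
    novel_target_fraction_neop: float = 0.15
    novel_target_fraction_3r: float = 0.30
    n_paralog_pairs_root: int = 3  # pre-WGD ("2R-analog") duplicated dev loci
    elements_per_2r_locus: int = 2
    dev_genes_per_chrom: int = 4
    novel_dev_per_chrom: int = 3
    cluster_span: int = 8_000
    motif: str = "TAATTA"
    motif_fraction: float = 0.20
    #: number of vertebrate elements evolved at neutral rate on the teleost
    #: stem (gain-by-extreme-divergence scenario); 0 disables
    n_diverged: int = 0
    indel_mode: bool = False

    def __post_init__(self):
        for p in (self.loss_prob_per_branch, self.wgd_retention, self.annotated_repeat_fraction,
                  self.motif_fraction, self.novel_target_fraction_neop, self.novel_target_fraction_3r):
            if not (0 <= p <= 1):
                raise ValueError("probabilities must be in [0, 1]")
        for scale in self.cne_rate_scales.values():
            if not (0 < scale <= 1):
                raise ValueError("cne rate scales must be in (0, 1]")
        if min(self.n_cne_vertebrate, self.n_cne_neopterygian, self.n_cne_3r) < 0:
            raise ValueError("element counts must be >= 0")

    def species_tree(self) -> SpeciesTree:
        return SpeciesTree(
            newick=self.newick,
            clade1_members=frozenset(self.clade1),
            clade2_members=frozenset(self.clade2),
            outgroup_ids=frozenset(self.outgroup),
            vertebrate_ids=frozenset(self.vertebrates),
        )


@dataclass
class Feature:
    fid: str
    kind: str  # gene | element | repeat
    chrom: str
    start: int
    end: int
    strand: str = "+"
    meta: dict = field(default_factory=dict)

    def __len__(self):
        return self.end - self.start


@dataclass
class _State:
    seqs: dict[str, np.ndarray]
    features: list[Feature]

    def clone(self) -> "_State":
        return _State(
            seqs={c: a.copy() for c, a in self.seqs.items()},
            features=[Feature(f.fid, f.kind, f.chrom, f.start, f.end, f.strand, _copy.deepcopy(f.meta)) for f in self.features],
        )


class CohortTruth:
    """Ground truth of one simulated cohort.

    ``elements``: per-species rows (species, chrom, start, end, strand,
    element_id, ancestral_id, copy, age_class, target_gene, motif).
    ``losses``: (branch, element_id) whole-element deletions.
    ``paralog_pairs``: (element_a, element_b, origin) with origin
    "2R-analog" (root-duplicated loci) or "3R" (WGD copies).
    """

    def __init__(self, elements: pd.DataFrame, losses: pd.DataFrame, paralog_pairs: pd.DataFrame, config: SimConfig):
        self.elements = elements
        self.losses = losses
        self.paralog_pairs = paralog_pairs
        self.config = config

    def elements_for(self, species: str) -> pd.DataFrame:
        return self.elements[self.elements.species == species]

    def species_with(self, element_id: str) -> set[str]:
        return set(self.elements[self.elements.element_id == element_id].species)

    def element_ids(self) -> list[str]:
        return sorted(self.elements.element_id.unique())

    def validate(self, genomes: GenomeSet) -> None:
        for row in self.elements.itertuples():
            seqs = genomes[row.species].sequences
            if row.chrom not in seqs or row.end > len(seqs[row.chrom]):
                raise AssertionError(f"truth element {row.element_id} outside {row.species} genome")
        pairs = {(a, b) for a, b in zip(self.paralog_pairs.element_a, self.paralog_pairs.element_b)}
        for a, b in pairs:
            if a == b:
                raise AssertionError("self paralog pair")


# --------------------------------------------------------------- mutation --

def _jc_mutate(arr: np.ndarray, p: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Mutate each site independently with its probability p (JC model)."""
    out = arr.copy()
    u = rng.random(len(arr))
    hit = (u < p) & (arr < 4)
    n = int(hit.sum())
    if n:
        shift = rng.integers(1, 4, size=n)
        out[hit] = (out[hit] + shift) % 4
    return out


def jc_p(branch_length: float, scale: float = 1.0) -> float:
    """Jukes-Cantor per-site difference probability for a branch."""
    return 0.75 * (1.0 - np.exp(-(4.0 / 3.0) * branch_length * scale))


def evolve_sequence(seq: str, branch_length: float, rate_scale_by_region=1.0, seed: int = 0) -> str:
    """Evolve a sequence along a branch under Jukes-Cantor substitutions.

    ``rate_scale_by_region`` is either a scalar or a list of
    ``(start, end, scale)`` regions (scale in (0, 1]); uncovered positions
    evolve at the neutral rate. Non-ACGT sites are left unchanged.
    Deterministic given ``seed``.
    """
    if branch_length < 0:
        raise ValueError("branch_length must be >= 0")
    arr = encode(seq)
    scales = np.ones(len(arr))
    if np.isscalar(rate_scale_by_region):
        scales[:] = float(rate_scale_by_region)
    else:
        for start, end, scale in rate_scale_by_region:
            if not (0 <= scale <= 1):
                raise ValueError("rate scales must be in [0, 1]")
            scales[start:end] = scale
    p = 0.75 * (1.0 - np.exp(-(4.0 / 3.0) * branch_length * scales))
    rng = np.random.default_rng(seed)
    return decode(_jc_mutate(arr, p, rng))


# ----------------------------------------------------------- state editing --

def _abs_subfeatures(f: Feature) -> list[tuple[int, int, float]]:
    """(start, end, scale) spans of a feature's conserved sub-structure."""
    out = []
    if f.kind == "gene":
        for rs, re_ in f.meta["exons"]:
            if f.strand == "+":
                out.append((f.start + rs, f.start + re_, f.meta["exon_scale"]))
            else:
                out.append((f.end - re_, f.end - rs, f.meta["exon_scale"]))
    elif f.kind == "element":
        out.append((f.start, f.end, f.meta["rate_scale"]))
        mrel = f.meta.get("motif_rel")
        if mrel is not None:
            mlen = f.meta["motif_len"]
            if f.strand == "+":
                out.append((f.start + mrel, f.start + mrel + mlen, 0.0))
            else:
                out.append((f.end - mrel - mlen, f.end - mrel, 0.0))
    return out


def _scale_arrays(state: _State, overrides: dict[str, float] | None = None) -> dict[str, np.ndarray]:
    scales = {c: np.ones(len(a)) for c, a in state.seqs.items()}
    for f in state.features:
        spans = _abs_subfeatures(f)
        if f.kind == "element" and overrides and f.meta["element_id"] in overrides:
            spans = [(spans[0][0], spans[0][1], overrides[f.meta["element_id"]])]
        for s, e, sc in spans:
            scales[f.chrom][s:e] = sc
    return scales


def _occupied(state: _State, chrom: str, pad: int) -> list[tuple[int, int]]:
    ivs = sorted((max(0, f.start - pad), f.end + pad) for f in state.features if f.chrom == chrom)
    merged: list[tuple[int, int]] = []
    for s, e in ivs:
        if merged and s <= merged[-1][1]:
            merged[-1] = (merged[-1][0], max(merged[-1][1], e))
        else:
            merged.append((s, e))
    return merged


def _find_free(state: _State, chrom: str, lo: int, hi: int, length: int, rng, pad: int = 200) -> int | None:
    L = len(state.seqs[chrom])
    lo, hi = max(0, lo), min(L, hi)
    occ = _occupied(state, chrom, pad)
    gaps = []
    pos = lo
    for s, e in occ:
        if e <= lo:
            continue
        if s >= hi:
            break
        if s - pos >= length:
            gaps.append((pos, s))
        pos = max(pos, e)
    if hi - pos >= length:
        gaps.append((pos, hi))
    gaps = [(s, e) for s, e in gaps if e - s >= length]
    if not gaps:
        return None
    weights = np.array([e - s - length + 1 for s, e in gaps], dtype=float)
    gi = int(rng.choice(len(gaps), p=weights / weights.sum()))
    s, e = gaps[gi]
    return int(rng.integers(s, e - length + 1))


def _shift_features(state: _State, chrom: str, at: int, delta: int) -> None:
    for f in state.features:
        if f.chrom == chrom and f.start >= at:
            f.start += delta
            f.end += delta


def _delete_span(state: _State, chrom: str, start: int, end: int) -> None:
    for f in state.features:
        if f.chrom == chrom and f.start < end and start < f.end and not (f.start >= start and f.end <= end):
            raise AssertionError("deletion would split a feature")
    state.features = [f for f in state.features if not (f.chrom == chrom and f.start >= start and f.end <= end)]
    state.seqs[chrom] = np.concatenate((state.seqs[chrom][:start], state.seqs[chrom][end:]))
    _shift_features(state, chrom, start, -(end - start))


def _invert_span(state: _State, chrom: str, start: int, end: int) -> None:
    seg = state.seqs[chrom][start:end]
    state.seqs[chrom][start:end] = revcomp_arr(seg)
    for f in state.features:
        if f.chrom == chrom and f.start >= start and f.end <= end:
            f.start, f.end = start + (end - f.end), start + (end - f.start)
            f.strand = "-" if f.strand == "+" else "+"


# ------------------------------------------------------------- root build --

def _random_seq(rng, n) -> np.ndarray:
    return rng.integers(0, 4, size=n).astype(np.uint8)


def _seq_without_motif(rng, n: int, motif_arr: np.ndarray) -> np.ndarray:
    for _ in range(50):
        s = _random_seq(rng, n)
        if not _contains(s, motif_arr):
            return s
    return s  # pragma: no cover - vanishingly unlikely


def _contains(arr: np.ndarray, pat: np.ndarray) -> bool:
    if len(arr) < len(pat):
        return False
    view = np.lib.stride_tricks.sliding_window_view(arr, len(pat))
    return bool((view == pat).all(axis=1).any())


class _Simulator:
    def __init__(self, config: SimConfig):
        self.cfg = config
        self.tree = dendropy.Tree.get(data=config.newick, schema="newick")
        self.node_index = {}
        for i, node in enumerate(self.tree.preorder_node_iter()):
            name = node.taxon.label if node.taxon else (node.label or f"node{i}")
            node._cne_name = name
            self.node_index[name] = i
        self.motif_arr = encode(config.motif)
        self.losses: list[tuple[str, str]] = []
        self.paralog_pairs: list[tuple[str, str, str]] = []
        self.pre_pairs: dict[str, str] = {}  # base gene id <-> 2R partner base id
        self.leaf_states: dict[str, _State] = {}
        self.elem_counter = {"vertebrate": 0, "neopterygian": 0, "3R": 0}
        self.diverged_ids: list[str] = []

    # -- rngs ---------------------------------------------------------------
    def rng_for(self, label: str, salt: int = 0) -> np.random.Generator:
        idx = self.node_index.get(label, 0)
        return np.random.default_rng(np.random.SeedSequence([self.cfg.seed % (2**31), 7919 + idx, salt]))

    def rng_named(self, tag: int) -> np.random.Generator:
        return np.random.default_rng(np.random.SeedSequence([self.cfg.seed % (2**31), tag]))

    # -- root ---------------------------------------------------------------
    def build_root(self) -> _State:
        cfg = self.cfg
        rng = self.rng_named(1)
        chrom_len = cfg.genome_length // cfg.n_chromosomes
        chroms = [f"chr{i + 1}" for i in range(cfg.n_chromosomes)]
        state = _State(seqs={c: _random_seq(rng, chrom_len) for c in chroms}, features=[])
        genes_per_chrom = cfg.n_genes // cfg.n_chromosomes if cfg.n_chromosomes else 0
        n_anc_chroms = max(1, cfg.n_chromosomes // 2)
        gid = 0
        exon_layout = [(0, 150), (350, 500), (700, 850)]
        gene_len = 850
        for ci, chrom in enumerate(chroms):
            if genes_per_chrom == 0:
                continue
            ancestral_chrom = ci < n_anc_chroms
            spacing = chrom_len // (genes_per_chrom + 1)
            n_dev = cfg.dev_genes_per_chrom if ancestral_chrom else cfg.novel_dev_per_chrom
            dev_idx = set(np.linspace(1, genes_per_chrom, num=min(n_dev, genes_per_chrom), dtype=int))
            for k in range(1, genes_per_chrom + 1):
                gid += 1
                base = f"g{gid:03d}"
                start = k * spacing + int(rng.integers(-spacing // 6, spacing // 6))
                start = max(0, min(chrom_len - gene_len, start))
                state.features.append(
                    Feature(
                        fid=f"gene:{base}",
                        kind="gene",
                        chrom=chrom,
                        start=start,
                        end=start + gene_len,
                        strand="+" if rng.random() < 0.5 else "-",
                        meta={
                            "gene_id": base,
                            "base": base,
                            "orthogroup": f"OG{gid:03d}",
                            "dev": k in dev_idx,
                            "ancestral_chrom": ancestral_chrom,
                            "exons": exon_layout,
                            "exon_scale": cfg.exon_rate_scale,
                        },
                    )
                )
        # pre-WGD ("2R-analog") paralogous dev locus pairs across the first two
        # ancestral chromosomes
        anc_dev = [f for f in state.features if f.kind == "gene" and f.meta["dev"] and f.meta["ancestral_chrom"]]
        by_chrom: dict[str, list[Feature]] = {}
        for f in anc_dev:
            by_chrom.setdefault(f.chrom, []).append(f)
        chroms_with_dev = sorted(by_chrom)
        n_pairs = 0
        if len(chroms_with_dev) >= 2:
            for a, b in zip(by_chrom[chroms_with_dev[0]], by_chrom[chroms_with_dev[1]]):
                if n_pairs >= cfg.n_paralog_pairs_root:
                    break
                self.pre_pairs[a.meta["base"]] = b.meta["base"]
                self.pre_pairs[b.meta["base"]] = a.meta["base"]
                n_pairs += 1
        # vertebrate-age elements (including duplicated 2R-pair elements)
        self.plant_elements(state, "vertebrate", cfg.n_cne_vertebrate, rng, novel_fraction=0.0)
        if cfg.n_diverged:
            vert_ids = [f.meta["element_id"] for f in state.features if f.kind == "element"]
            self.diverged_ids = vert_ids[: cfg.n_diverged]
        return state

    # -- planting -----------------------------------------------------------
    def _new_elem_id(self, age: str) -> str:
        self.elem_counter[age] += 1
        prefix = {"vertebrate": "v", "neopterygian": "n", "3R": "r"}[age]
        return f"{prefix}{self.elem_counter[age]:03d}"

    def plant_elements(self, state: _State, age: str, count: int, rng, novel_fraction: float) -> None:
        cfg = self.cfg
        dev = [f for f in state.features if f.kind == "gene" and f.meta["dev"]]
        anc_loci = [f for f in dev if f.meta["ancestral_chrom"]]
        nov_loci = [f for f in dev if not f.meta["ancestral_chrom"]]
        scale = cfg.cne_rate_scales[age]
        # paired 2R elements are planted first (vertebrate age only)
        planted = 0
        if age == "vertebrate" and self.pre_pairs:
            done = set()
            for base_a, base_b in sorted(self.pre_pairs.items()):
                if base_a in done or planted + 2 > count:
                    continue
                done.update((base_a, base_b))
                fa = next(f for f in anc_loci if f.meta["base"] == base_a)
                fb = next(f for f in anc_loci if f.meta["base"] == base_b)
                for _ in range(cfg.elements_per_2r_locus):
                    if planted + 2 > count:
                        break
                    length = int(rng.integers(*cfg.cne_length_range))
                    seq = _seq_without_motif(rng, length, self.motif_arr)
                    eid_a = self._plant_one(state, age, fa, seq, scale, rng)
                    seq_b = _jc_mutate(seq, np.full(length, 0.05), rng)
                    eid_b = self._plant_one(state, age, fb, seq_b, scale, rng)
                    if eid_a and eid_b:
                        self.paralog_pairs.append((eid_a, eid_b, "2R-analog"))
                        planted += 2
        i = 0
        while planted < count:
            i += 1
            use_novel = nov_loci and rng.random() < novel_fraction
            loci = nov_loci if use_novel else (anc_loci or nov_loci)
            if not loci:
                target = None
            else:
                target = loci[int(rng.integers(0, len(loci)))]
            length = int(rng.integers(*cfg.cne_length_range))
            seq = _seq_without_motif(rng, length, self.motif_arr)
            if self._plant_one(state, age, target, seq, scale, rng):
                planted += 1
            elif i > 20 * count:
                raise RuntimeError("could not place all elements; genome too crowded")

    def _plant_one(self, state: _State, age: str, target: Feature | None, seq: np.ndarray, scale, rng) -> str | None:
        cfg = self.cfg
        length = len(seq)
        if target is not None:
            chrom = target.chrom
            lo = target.start - cfg.cluster_span - length
            hi = target.end + cfg.cluster_span
        else:
            chrom = list(state.seqs)[int(rng.integers(0, len(state.seqs)))]
            lo, hi = 0, len(state.seqs[chrom])
        pos = _find_free(state, chrom, lo, hi, length, rng)
        if pos is None:
            pos = _find_free(state, chrom, lo - 4 * cfg.cluster_span, hi + 4 * cfg.cluster_span, length, rng)
        if pos is None:
            return None
        motif_rel = None
        if cfg.motif and rng.random() < cfg.motif_fraction:
            motif_rel = (length - len(cfg.motif)) // 2
            seq = seq.copy()
            seq[motif_rel : motif_rel + len(cfg.motif)] = self.motif_arr
        state.seqs[chrom][pos : pos + length] = seq
        eid = self._new_elem_id(age)
        state.features.append(
            Feature(
                fid=f"elem:{eid}",
                kind="element",
                chrom=chrom,
                start=pos,
                end=pos + length,
                strand="+",
                meta={
                    "element_id": eid,
                    "ancestral_id": eid,
                    "copy": "a",
                    "age": age,
                    "target": target.meta["gene_id"] if target is not None else "",
                    "rate_scale": scale,
                    "motif_rel": motif_rel,
                    "motif_len": len(cfg.motif),
                },
            )
        )
        return eid

    # -- branch evolution ---------------------------------------------------
    def evolve_branch(self, state: _State, branch_length: float, child_name: str, is_leaf: bool) -> None:
        cfg = self.cfg
        rng = self.rng_for(child_name)
        overrides = None
        if self.diverged_ids and child_name == cfg.wgd_branch:
            overrides = {eid: 1.0 for eid in self.diverged_ids}
        scales = _scale_arrays(state, overrides)
        for chrom in state.seqs:
            p = 0.75 * (1.0 - np.exp(-(4.0 / 3.0) * branch_length * scales[chrom]))
            state.seqs[chrom] = _jc_mutate(state.seqs[chrom], p, rng)
        # element losses
        doomed = [f for f in state.features if f.kind == "element" and rng.random() < cfg.loss_prob_per_branch]
        for f in sorted(doomed, key=lambda f: (f.chrom, -f.start)):
            self.losses.append((child_name, f.meta["element_id"]))
            _delete_span(state, f.chrom, f.start, f.end)
        # inversions
        for _ in range(rng.poisson(cfg.inversion_rate)):
            self._try_inversion(state, rng)
        # interspersed repeats on terminal branches
        if is_leaf and cfg.repeat_density > 0:
            genome_mb = sum(len(a) for a in state.seqs.values()) / 1e6
            n_copies = rng.poisson(cfg.repeat_density * genome_mb)
            consensus = self.repeat_consensus
            for r in range(n_copies):
                chrom = self._weighted_chrom(state, rng)
                pos = _find_free(state, chrom, 0, len(state.seqs[chrom]), cfg.repeat_length, rng)
                if pos is None:
                    continue
                seq = _jc_mutate(consensus, np.full(cfg.repeat_length, cfg.repeat_divergence), rng)
                if rng.random() < 0.5:
                    seq = revcomp_arr(seq)
                state.seqs[chrom][pos : pos + cfg.repeat_length] = seq
                state.features.append(
                    Feature(
                        fid=f"rep:{child_name}:{r}",
                        kind="repeat",
                        chrom=chrom,
                        start=pos,
                        end=pos + cfg.repeat_length,
                        meta={"family": "simrep1", "annotated": bool(rng.random() < cfg.annotated_repeat_fraction)},
                    )
                )

    def _weighted_chrom(self, state: _State, rng) -> str:
        names = sorted(state.seqs)
        w = np.array([len(state.seqs[c]) for c in names], dtype=float)
        return names[int(rng.choice(len(names), p=w / w.sum()))]

    def _try_inversion(self, state: _State, rng) -> None:
        for _ in range(25):
            chrom = self._weighted_chrom(state, rng)
            L = len(state.seqs[chrom])
            size = int(rng.integers(15_000, 50_000))
            if L <= size + 2:
                continue
            start = int(rng.integers(0, L - size))
            end = start + size
            ok = all(not (f.start < b <= f.end) for f in state.features if f.chrom == chrom for b in (start, end))
            if ok:
                _invert_span(state, chrom, start, end)
                return

    # -- WGD ----------------------------------------------------------------
    def apply_wgd(self, state: _State, rng) -> None:
        cfg = self.cfg
        new_feats: list[Feature] = []
        for chrom in sorted(state.seqs):
            state.seqs[chrom + "_b"] = state.seqs[chrom].copy()
        for f in list(state.features):
            fb = Feature(f.fid + "_b", f.kind, f.chrom + "_b", f.start, f.end, f.strand, _copy.deepcopy(f.meta))
            if fb.kind == "gene":
                fb.meta["gene_id"] = f.meta["gene_id"] + "b"
            elif fb.kind == "element":
                fb.meta["element_id"] = f.meta["element_id"] + "b"
                fb.meta["copy"] = "b"
                if fb.meta["target"]:
                    fb.meta["target"] = fb.meta["target"] + "b"
            new_feats.append(fb)
        state.features.extend(new_feats)
        # per-locus retention on the duplicated copy: a dev gene and its
        # satellite elements are one retention unit; other genes independent
        genes_b = [f for f in state.features if f.kind == "gene" and f.chrom.endswith("_b")]
        elements_b = [f for f in state.features if f.kind == "element" and f.chrom.endswith("_b")]
        to_delete: list[Feature] = []
        retained_genes: set[str] = set()
        for g in sorted(genes_b, key=lambda f: f.meta["gene_id"]):
            keep = rng.random() < cfg.wgd_retention
            members = [g] + [e for e in elements_b if e.meta["target"] == g.meta["gene_id"]]
            if keep:
                retained_genes.add(g.meta["gene_id"])
            else:
                to_delete.extend(members)
        orphan_b = [e for e in elements_b if not e.meta["target"]]
        for e in orphan_b:
            if not (rng.random() < cfg.wgd_retention):
                to_delete.append(e)
        for f in sorted(to_delete, key=lambda f: (f.chrom, -f.start)):
            _delete_span(state, f.chrom, f.start, f.end)
        for f in state.features:
            if f.kind == "element" and f.chrom.endswith("_b"):
                self.paralog_pairs.append((f.meta["ancestral_id"], f.meta["element_id"], "3R"))

    # -- main walk ----------------------------------------------------------
    def run(self) -> None:
        cfg = self.cfg
        self.repeat_consensus = _random_seq(self.rng_named(2), cfg.repeat_length)
        root_state = self.build_root()
        wgd_found = [False]

        def walk(node, state: _State):
            for child in node.child_nodes():
                name = child._cne_name
                st = state.clone()
                self.evolve_branch(st, child.edge.length or 0.0, name, child.is_leaf())
                if name == cfg.wgd_branch:
                    wgd_found[0] = True
                    self.apply_wgd(st, self.rng_for(name, salt=1))
                    self.plant_elements(st, "3R", cfg.n_cne_3r, self.rng_named(4), cfg.novel_target_fraction_3r)
                if name == cfg.neop_branch:
                    self.plant_elements(
                        st, "neopterygian", cfg.n_cne_neopterygian, self.rng_named(3), cfg.novel_target_fraction_neop
                    )
                if child.is_leaf():
                    self.leaf_states[name] = st
                else:
                    walk(child, st)

        walk(self.tree.seed_node, root_state)
        if (cfg.n_cne_3r or cfg.wgd_retention < 1) and not wgd_found[0]:
            raise ValueError(f"wgd_branch {cfg.wgd_branch!r} not found in tree")


def _materialize(sim: _Simulator) -> tuple[GenomeSet, OrthologyTable, CohortTruth]:
    cfg = sim.cfg
    genomes = GenomeSet()
    truth_rows = []
    ortho_rows = []
    for sp, state in sorted(sim.leaf_states.items()):
        seqs = {c: decode(a) for c, a in sorted(state.seqs.items())}
        exons, repeats, genes = [], [], {}
        present_bases: dict[str, list[str]] = {}
        for f in sorted(state.features, key=lambda f: (f.chrom, f.start)):
            if f.kind == "gene":
                gid = f.meta["gene_id"]
                genes[gid] = Interval(f.chrom, f.start, f.end, f.strand)
                present_bases.setdefault(f.meta["base"], []).append(gid)
                for s, e, _ in _abs_subfeatures(f):
                    exons.append(Interval(f.chrom, s, e, f.strand))
            elif f.kind == "repeat" and f.meta["annotated"]:
                repeats.append(Interval(f.chrom, f.start, f.end))
            elif f.kind == "element":
                truth_rows.append(
                    {
                        "species": sp,
                        "chrom": f.chrom,
                        "start": f.start,
                        "end": f.end,
                        "strand": f.strand,
                        "element_id": f.meta["element_id"],
                        "ancestral_id": f.meta["ancestral_id"],
                        "copy": f.meta["copy"],
                        "age_class": f.meta["age"],
                        "target_gene": f.meta["target"],
                        "motif": f.meta["motif_rel"] is not None,
                    }
                )
        genomes[sp] = SpeciesGenome(sequences=seqs, exons=exons, repeats=repeats, genes=genes)
        for f in sorted(state.features, key=lambda f: f.meta.get("gene_id", "")):
            if f.kind != "gene":
                continue
            base = f.meta["base"]
            gid = f.meta["gene_id"]
            partners = [g for g in present_bases.get(base, []) if g != gid]
            origin = "post-WGD" if partners else "none"
            pre_base = sim.pre_pairs.get(base)
            if pre_base and pre_base in present_bases:
                partners += present_bases[pre_base]
                if origin == "none":
                    origin = "pre-WGD"
            ortho_rows.append(
                {
                    "species_id": sp,
                    "gene_id": gid,
                    "orthogroup_id": f.meta["orthogroup"],
                    "paralog_partner_ids": ",".join(sorted(partners)),
                    "paralog_origin": origin,
                }
            )
    elements = pd.DataFrame(
        truth_rows,
        columns=["species", "chrom", "start", "end", "strand", "element_id", "ancestral_id", "copy", "age_class", "target_gene", "motif"],
    )
    losses = pd.DataFrame(sim.losses, columns=["branch", "element_id"])
    pairs = pd.DataFrame(sorted(set(sim.paralog_pairs)), columns=["element_a", "element_b", "origin"])
    ortho = OrthologyTable(pd.DataFrame(ortho_rows, columns=OrthologyTable.COLUMNS)) if ortho_rows else OrthologyTable(
        pd.DataFrame(columns=OrthologyTable.COLUMNS)
    )
    truth = CohortTruth(elements, losses, pairs, cfg)
    return genomes, ortho, truth


def simulate_cohort(config: SimConfig, out_dir=None):
    """Simulate a cohort; returns (GenomeSet, SpeciesTree, OrthologyTable, CohortTruth).

    With ``out_dir`` the cohort is also written to disk: per-species FASTA
    and BED annotations, the orthology TSV, the newick tree, and the truth
    tables. Deterministic given ``config.seed``.
    """
    sim = _Simulator(config)
    sim.run()
    genomes, ortho, truth = _materialize(sim)
    tree = config.species_tree()
    truth.validate(genomes)
    if out_dir is not None:
        _write_cohort(out_dir, genomes, tree, ortho, truth)
    return genomes, tree, ortho, truth


def _write_cohort(out_dir, genomes: GenomeSet, tree: SpeciesTree, ortho: OrthologyTable, truth: CohortTruth) -> None:
    from . import io as cio

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for sp, g in sorted(genomes.items()):
        cio.write_fasta(g.sequences, out / f"{sp}.fa")
        cio.write_bed(g.exons, out / f"{sp}.exons.bed")
        cio.write_bed(g.repeats, out / f"{sp}.repeats.bed")
        gene_ids = sorted(g.genes)
        cio.write_bed([g.genes[gid] for gid in gene_ids], out / f"{sp}.genes.bed", names=gene_ids)
    (out / "tree.nwk").write_text(tree.newick + "\n")
    ortho.df.to_csv(out / "orthology.tsv", sep="\t", index=False)
    truth.elements.to_csv(out / "truth_elements.tsv", sep="\t", index=False)
    truth.losses.to_csv(out / "truth_losses.tsv", sep="\t", index=False)
    truth.paralog_pairs.to_csv(out / "truth_paralogs.tsv", sep="\t", index=False)
    cfg = asdict(truth.config)
    cfg["cne_length_range"] = list(cfg["cne_length_range"])
    import yaml

    (out / "config.yaml").write_text(yaml.safe_dump(cfg))
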