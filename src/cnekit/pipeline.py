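"""End-to-end pipeline: simulate -> align -> detect -> search -> ancestry ->
zones -> associate -> paralogs -> phylo -> motif.

One config drives every stage; each stage's parameters mirror the Params
types of its module. Outputs are written per stage with a JSON manifest of
content hashes; expensive stages (pairwise nets, presence matrix) are
reused from disk when their config-section hash is unchanged.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import io as cio
from .align import AlignerParams, hard_mask, two_round_align
from .ancestry import (
    AncestryParams,
    AtCNESet,
    categorize_origin,
    conservation_by_category,
    infer_ancestral_set,
    loss_rates,
    zone_profile,
)
from .associate import (
    AssocParams,
    BootstrapResult,
    associate,
    associations_frame,
    bootstrap_null,
    candidate_genes,
    classify_targets,
    select_targets,
    synteny_scores,
    vcne_target_orthogroups,
)
from .chain import chain_blocks, net_blocks, net_chains
from .detect import CNESet, DetectParams, detect_cnes
from .model import GenomeSet, OrthologyTable, SpeciesTree
from .motif import central_element_fraction, positional_distribution, scan_consensus
from .paralogy import cluster_origin_shares, common_clusters, member_category_shares, paralogy_clusters, self_hits
from .phylo import build_supermatrix, extract_marker_seqs, nj_tree, rf_distance, universal_single_copy
from .search import GenomeIndex, PresenceMatrix, SearchParams, build_presence_matrix
from .simulate import SimConfig, simulate_cohort

log = logging.getLogger(__name__)

STAGES = ("simulate", "align", "detect", "search", "ancestry", "zones", "associate", "paralogs", "phylo", "motif")


@dataclass
class PipelineConfig:
    simulate: SimConfig = field(default_factory=SimConfig)
    aligner: AlignerParams = field(default_factory=AlignerParams)
    chain_gap_open: float = 50.0
    chain_per_bp_gap_cost: float = 0.5
    chain_max_gap: int = 10_000
    detect: DetectParams = field(default_factory=DetectParams)
    search: SearchParams = field(default_factory=SearchParams)
    assoc: AssocParams = field(default_factory=AssocParams)
    zone_size: int = 50_000
    vcne_min_synteny_species: int = 2
    motif: str = "TAATTA"
    #: focal reference pairs (reference first): clade-1 pair then clade-2 pair
    focal_pair_1: tuple[str, str] = ("dre", "ame")
    focal_pair_2: tuple[str, str] = ("tru", "sau")
    vcne_pair: tuple[str, str] = ("hsa", "cmi")

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        cfg = cls()
        if "simulate" in d:
            cfg.simulate = SimConfig(**{**d["simulate"]})
        if "aligner" in d:
            cfg.aligner = AlignerParams(**d["aligner"])
        if "detect" in d:
            cfg.detect = DetectParams(**d["detect"])
        if "search" in d:
            cfg.search = SearchParams(**d["search"])
        if "associate" in d:
            cfg.assoc = AssocParams(**d["associate"])
        for key in ("chain_gap_open", "chain_per_bp_gap_cost", "chain_max_gap", "zone_size",
                    "vcne_min_synteny_species", "motif"):
            if key in d:
                setattr(cfg, key, d[key])
        for key in ("focal_pair_1", "focal_pair_2", "vcne_pair"):
            if key in d:
                setattr(cfg, key, tuple(d[key]))
        return cfg

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})

    def section_hash(self, *sections: str) -> str:
        payload = []
        for s in sections:
            v = getattr(self, s)
            if dataclasses.is_dataclass(v):
                v = dataclasses.asdict(v)
            payload.append((s, v))
        return hashlib.sha256(repr(payload).encode()).hexdigest()[:16]


@dataclass
class PipelineResult:
    config: PipelineConfig
    genomes: GenomeSet = None
    tree: SpeciesTree = None
    orthology: OrthologyTable = None
    truth: object = None
    nets: dict = field(default_factory=dict)  # (ref, query) -> net blocks
    cne_sets: dict = field(default_factory=dict)  # name -> CNESet (zcne, fcne, vcne)
    presence: PresenceMatrix = None
    atcnes: AtCNESet = None
    loss_table: object = None
    zones: object = None
    conservation: dict = field(default_factory=dict)
    vcne_associations: dict = field(default_factory=dict)
    vcne_target_ogs: set = field(default_factory=set)
    associations: dict = field(default_factory=dict)
    bootstrap: BootstrapResult = None
    self_hit_pairs: dict = field(default_factory=dict)
    clusters: dict = field(default_factory=dict)  # group -> clusters
    common_cluster_pairs: list = field(default_factory=list)
    universal: dict = field(default_factory=dict)
    supermatrix: object = None
    nj_newick: str = ""
    rf_vs_true: int = -1
    motif_fraction: float = float("nan")
    motif_central_fraction: float = float("nan")
    motif_positional: object = None
    manifest: dict = field(default_factory=dict)


def _sha(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()[:16]


class Pipeline:
    def __init__(self, config: PipelineConfig, out_dir=None):
        self.cfg = config
        self.out = Path(out_dir) if out_dir else None
        if self.out:
            self.out.mkdir(parents=True, exist_ok=True)
        self.res = PipelineResult(config)
        self._manifest_path = self.out / "manifest.json" if self.out else None
        self._old_manifest = {}
        if self._manifest_path and self._manifest_path.exists():
            self._old_manifest = json.loads(self._manifest_path.read_text())

    # ---------------------------------------------------------- plumbing --
    def _record(self, stage: str, t0: float, outputs: list[Path], cfg_hash: str, cached: bool = False) -> None:
        self.res.manifest[stage] = {
            "runtime_s": round(time.time() - t0, 2),
            "config_hash": cfg_hash,
            "seed": self.cfg.simulate.seed,
            "cached": cached,
            "outputs": {p.name: _sha(p) for p in outputs if p is not None and p.exists()},
        }
        if self._manifest_path:
            self._manifest_path.write_text(json.dumps(self.res.manifest, indent=1, sort_keys=True))

    def _cache_ok(self, stage: str, cfg_hash: str, files: list[Path]) -> bool:
        old = self._old_manifest.get(stage)
        return (
            old is not None
            and old.get("config_hash") == cfg_hash
            and self.out is not None
            and all(f.exists() for f in files)
        )

    # ------------------------------------------------------------ stages --
    def stage_simulate(self):
        t0 = time.time()
        h = self.cfg.section_hash("simulate")
        cohort_dir = self.out / "cohort" if self.out else None
        g, tree, ortho, truth = simulate_cohort(self.cfg.simulate, out_dir=cohort_dir)
        self.res.genomes, self.res.tree, self.res.orthology, self.res.truth = g, tree, ortho, truth
        outs = sorted(cohort_dir.glob("*")) if cohort_dir else []
        self._record("simulate", t0, outs, h)

    def _pair_net(self, ref_sp: str, query_sp: str):
        cfg = self.cfg
        g = self.res.genomes
        ref, qry = g[ref_sp], g[query_sp]
        ref_seqs = hard_mask(ref.sequences, ref.repeats)
        qry_seqs = hard_mask(qry.sequences, qry.repeats)
        blocks = two_round_align(ref_seqs, qry_seqs, cfg.aligner)
        chains = chain_blocks(blocks, cfg.chain_gap_open, cfg.chain_per_bp_gap_cost, cfg.chain_max_gap)
        return net_blocks(net_chains(chains, cfg.aligner))

    def stage_align(self):
        t0 = time.time()
        h = self.cfg.section_hash("simulate", "aligner", "chain_gap_open", "chain_per_bp_gap_cost", "chain_max_gap")
        pairs = [tuple(self.cfg.focal_pair_1), tuple(self.cfg.focal_pair_2), tuple(self.cfg.vcne_pair)]
        outs = []
        cached = True
        for ref_sp, query_sp in pairs:
            path = self.out / f"net.{ref_sp}-{query_sp}.axt" if self.out else None
            if path is not None and self._cache_ok("align", h, [path]):
                qsizes = {c: len(s) for c, s in self.res.genomes[query_sp].sequences.items()}
                self.res.nets[(ref_sp, query_sp)] = cio.read_axt(path, query_sizes=qsizes)
                outs.append(path)
                continue
            cached = False
            net = self._pair_net(ref_sp, query_sp)
            self.res.nets[(ref_sp, query_sp)] = net
            if path is not None:
                qsizes = {c: len(s) for c, s in self.res.genomes[query_sp].sequences.items()}
                cio.write_axt(net, path, query_sizes=qsizes)
                outs.append(path)
        self._record("align", t0, outs, h, cached=cached)

    def stage_detect(self):
        t0 = time.time()
        cfg = self.cfg
        h = self.cfg.section_hash("simulate", "aligner", "detect", "search")
        names = {"zcne": cfg.focal_pair_1, "fcne": cfg.focal_pair_2, "vcne": cfg.vcne_pair}
        outs = []
        for name, (ref_sp, query_sp) in names.items():
            cset = detect_cnes(
                self.res.nets[(ref_sp, query_sp)],
                self.res.genomes[ref_sp],
                self.res.genomes[query_sp],
                ref_sp,
                query_sp,
                cfg.detect,
                cfg.search,
                id_prefix=f"{name}_",
            )
            self.res.cne_sets[name] = cset
            if self.out:
                path = self.out / f"{name}.tsv"
                cset.to_frame().to_csv(path, sep="\t", index=False)
                outs.append(path)
        self._record("detect", t0, outs, h)

    def stage_search(self):
        t0 = time.time()
        h = self.cfg.section_hash("simulate", "aligner", "detect", "search")
        path = self.out / "presence.tsv" if self.out else None
        self.res.presence = build_presence_matrix(
            [self.res.cne_sets[n] for n in ("zcne", "fcne", "vcne")],
            self.res.genomes,
            self.cfg.search,
        )
        if path is not None:
            self.res.presence.to_tsv(path)
        self._record("search", t0, [path] if path else [], h)

    def _ancestry_params(self) -> AncestryParams:
        tree = self.res.tree
        return AncestryParams(
            clade1=tree.clade1_members,
            clade2=tree.clade2_members,
            neopterygian_outgroup=tree.outgroup_ids,
            vertebrate_outgroup=tree.vertebrate_ids,
            zone_size=self.cfg.zone_size,
        )

    def stage_ancestry(self):
        t0 = time.time()
        h = self.cfg.section_hash("simulate", "detect", "search", "zone_size")
        params = self._ancestry_params()
        atcnes = infer_ancestral_set(self.res.cne_sets["zcne"], self.res.cne_sets["fcne"], self.res.presence, params)
        categorize_origin(atcnes, self.res.presence, params)
        self.res.atcnes = atcnes
        teleosts = sorted(self.res.tree.teleost_ids)
        self.res.loss_table = loss_rates(atcnes, self.res.presence, teleosts)
        self.res.conservation = conservation_by_category(atcnes, self.res.presence, self.res.genomes)
        outs = []
        if self.out:
            p1 = self.out / "atcnes.tsv"
            atcnes.to_frame().to_csv(p1, sep="\t", index=False)
            p2 = self.out / "loss_rates.tsv"
            self.res.loss_table.to_csv(p2, sep="\t", index=False)
            outs = [p1, p2]
        self._record("ancestry", t0, outs, h)

    def stage_zones(self):
        t0 = time.time()
        h = self.cfg.section_hash("simulate", "zone_size")
        ref_sp = self.cfg.focal_pair_1[0]
        self.res.zones = zone_profile(self.res.atcnes, self.res.genomes[ref_sp], self._ancestry_params(), ref_species=ref_sp)
        outs = []
        if self.out:
            p = self.out / "zones.tsv"
            self.res.zones.table.to_csv(p, sep="\t", index=False)
            outs = [p]
        self._record("zones", t0, outs, h)

    def stage_associate(self):
        t0 = time.time()
        cfg = self.cfg
        h = self.cfg.section_hash("simulate", "search", "assoc")
        # vertebrate reference target set, built with the same machinery but a
        # permissive species cutoff (few outgroup genomes carry the vCNEs)
        vparams = AssocParams(
            window=cfg.assoc.window,
            min_synteny_species=cfg.vcne_min_synteny_species,
            n_bootstrap=cfg.assoc.n_bootstrap,
            seed=cfg.assoc.seed,
        )
        vcne_ids = [r.id for r in self.res.cne_sets["vcne"]]
        self.res.vcne_associations = associate(vcne_ids, self.res.presence, self.res.genomes, self.res.orthology, vparams)
        self.res.vcne_target_ogs = vcne_target_orthogroups(self.res.vcne_associations)
        at_ids = [m.id for m in self.res.atcnes]
        assocs = associate(at_ids, self.res.presence, self.res.genomes, self.res.orthology, cfg.assoc)
        classify_targets(assocs, self.res.vcne_target_ogs)
        self.res.associations = assocs
        self.res.bootstrap = self.bootstrap_result(assocs)
        outs = []
        if self.out:
            p = self.out / "associations.tsv"
            associations_frame(assocs).to_csv(p, sep="\t", index=False)
            outs = [p]
        self._record("associate", t0, outs, h)

    def bootstrap_result(self, assocs) -> BootstrapResult:
        """Combined bootstrap z over the reference species gene pools."""
        observed = sum(1 for a in assocs.values() if a.target_class == "ancestral")
        sizes = []
        pools = {}
        for cid, a in assocs.items():
            ref_sp = self.res.presence.ref_species[cid]
            cands = candidate_genes(cid, self.res.presence, self.res.genomes, self.cfg.assoc.window).get(ref_sp, [])
            if a.target_class in ("ancestral", "novel"):
                pools.setdefault(ref_sp, []).append(len(cands))
        mean = 0.0
        var = 0.0
        for i, (ref_sp, sp_sizes) in enumerate(sorted(pools.items())):
            genes = self.res.genomes[ref_sp].genes
            og = {g: self.res.orthology.orthogroup(ref_sp, g) for g in genes}
            params = AssocParams(
                window=self.cfg.assoc.window,
                min_synteny_species=self.cfg.assoc.min_synteny_species,
                n_bootstrap=self.cfg.assoc.n_bootstrap,
                seed=self.cfg.assoc.seed + i,
            )
            r = bootstrap_null(0, sp_sizes, sorted(genes), og, self.res.vcne_target_ogs, params)
            mean += r.mean
            var += r.sd**2
        sd = var**0.5
        z = float("inf") if sd == 0 else (observed - mean) / sd
        return BootstrapResult(observed, mean, sd, z, infinite=sd == 0)

    def shuffled_bootstrap_z(self, seed_offset: int = 1, n_shuffles: int = 3) -> BootstrapResult:
        """Calibration: relocate every associated element to a random gene
        neighborhood (consistently across species, anchored on gene ids) and
        recompute the ancestral-count z against the same null. A single
        relocation is itself one binomial draw, so the reported z is the
        mean over ``n_shuffles`` independent relocations."""
        null = self.bootstrap_result(self.res.associations)
        zs = []
        obs = []
        for rep in range(n_shuffles):
            o = self._one_shuffle(seed_offset * 1000 + rep)
            obs.append(o)
            if null.sd > 0:
                zs.append((o - null.mean) / null.sd)
        if null.sd == 0:
            return BootstrapResult(int(np.mean(obs)), null.mean, null.sd, float("inf"), infinite=True)
        return BootstrapResult(int(np.mean(obs)), null.mean, null.sd, float(np.mean(zs)))

    def _one_shuffle(self, seed_offset: int) -> int:
        rng = np.random.default_rng(self.cfg.assoc.seed + 10_000 + seed_offset)
        observed = 0
        for cid, a in self.res.associations.items():
            if a.target_class not in ("ancestral", "novel"):
                continue
            ref_sp = self.res.presence.ref_species[cid]
            bases = sorted({g.rstrip("b") for g in self.res.genomes[ref_sp].genes})
            base = bases[int(rng.integers(0, len(bases)))]
            delta = int(rng.integers(-20_000, 20_000))
            fake_cands = {}
            for sp in self.res.presence.species:
                if not self.res.presence.present(cid, sp):
                    continue
                genes = self.res.genomes[sp].genes
                anchor = base if base in genes else (base + "b" if base + "b" in genes else None)
                if anchor is None:
                    continue
                g_iv = genes[anchor]
                L = len(self.res.genomes[sp].sequences[g_iv.chrom])
                start = min(max(0, g_iv.start + delta), max(0, L - 100))
                from .model import Interval

                fake_loc = Interval(g_iv.chrom, start, min(L, start + 100))
                lo, hi = fake_loc.start - self.cfg.assoc.window, fake_loc.end + self.cfg.assoc.window
                cands = []
                for gid, iv in genes.items():
                    if iv.chrom != fake_loc.chrom or iv.end <= lo or iv.start >= hi:
                        continue
                    dist = 0 if iv.overlaps(fake_loc) else max(iv.start - fake_loc.end, fake_loc.start - iv.end)
                    cands.append((gid, int(dist)))
                if cands:
                    cands.sort(key=lambda t: (t[1], t[0]))
                    fake_cands[sp] = cands
            scored = synteny_scores(fake_cands, self.res.orthology)
            assoc = select_targets(cid, scored, self.cfg.assoc, ref_sp, fake_cands, self.res.orthology)
            if assoc.orthogroups and set(assoc.orthogroups) & self.res.vcne_target_ogs:
                observed += 1
        return observed

    def stage_paralogs(self):
        t0 = time.time()
        h = self.cfg.section_hash("simulate", "search", "assoc")
        z_ref = self.cfg.focal_pair_1[0]
        v_ref = self.cfg.vcne_pair[0]
        at_z = CNESet(z_ref, [m.record for m in self.res.atcnes.by_ref_species(z_ref)])
        pairs_z = self_hits(at_z, self.res.genomes, self.cfg.search)
        self.res.self_hit_pairs["atcne"] = pairs_z
        self.res.clusters["atcne"] = paralogy_clusters(pairs_z, self.res.associations, self.res.orthology, z_ref, "atpc")
        vset = self.res.cne_sets["vcne"]
        pairs_v = self_hits(vset, self.res.genomes, self.cfg.search)
        self.res.self_hit_pairs["vcne"] = pairs_v
        self.res.clusters["vcne"] = paralogy_clusters(pairs_v, self.res.vcne_associations, self.res.orthology, v_ref, "vpc")
        self.res.common_cluster_pairs = common_clusters(self.res.clusters["atcne"], self.res.clusters["vcne"])
        outs = []
        if self.out:
            import pandas as pd

            rows = [
                {"cluster_id": c.cluster_id, "group": grp, "members": ",".join(c.members), "origin": c.origin}
                for grp, clusters in sorted(self.res.clusters.items())
                for c in clusters
            ]
            p = self.out / "paralogy_clusters.tsv"
            pd.DataFrame(rows, columns=["cluster_id", "group", "members", "origin"]).to_csv(p, sep="\t", index=False)
            outs = [p]
        self._record("paralogs", t0, outs, h)

    def stage_phylo(self):
        t0 = time.time()
        h = self.cfg.section_hash("simulate", "search")
        all_species = sorted(self.res.genomes)
        teleosts = sorted(self.res.tree.teleost_ids)
        self.res.universal["with_outgroup"] = universal_single_copy(self.res.presence, all_species)
        self.res.universal["teleost_only"] = universal_single_copy(self.res.presence, teleosts)
        # prefer the outgroup-inclusive marker design; fall back to the
        # teleost-only set when no marker survives in every outgroup
        markers = self.res.universal["with_outgroup"] or self.res.universal["teleost_only"]
        outs = []
        if len(markers) >= 1:
            seqs = extract_marker_seqs(markers, self.res.presence, self.res.genomes, flank=50)
            self.res.supermatrix = build_supermatrix(seqs, gap_threshold=0.5)
            if len(self.res.supermatrix.species) >= 4:
                self.res.nj_newick = nj_tree(self.res.supermatrix)
                self.res.rf_vs_true = rf_distance(self.res.nj_newick, self.res.tree.newick)
            if self.out:
                p1 = self.out / "supermatrix.phy"
                self.res.supermatrix.to_phylip(p1)
                p2 = self.out / "nj_tree.nwk"
                p2.write_text(self.res.nj_newick + "\n")
                outs = [p1, p2]
        self._record("phylo", t0, outs, h)

    def stage_motif(self):
        t0 = time.time()
        h = self.cfg.section_hash("simulate", "detect", "motif")
        members = list(self.res.atcnes)
        occs, frac = scan_consensus(members, self.res.genomes, self.cfg.motif)
        self.res.motif_fraction = frac
        self.res.motif_positional = positional_distribution(occs)
        self.res.motif_central_fraction = central_element_fraction(members, self.res.genomes, self.cfg.motif)
        outs = []
        if self.out:
            import pandas as pd

            p = self.out / "motif_occurrences.tsv"
            pd.DataFrame(
                [
                    {"cne_id": o.cne_id, "motif": o.motif, "offset": o.offset, "strand": o.strand,
                     "relative_position": round(o.relative_position, 4)}
                    for o in occs
                ]
            ).to_csv(p, sep="\t", index=False)
            outs = [p]
        self._record("motif", t0, outs, h)

    def run(self, stages=None) -> PipelineResult:
        todo = list(stages) if stages else list(STAGES)
        unknown = set(todo) - set(STAGES)
        if unknown:
            raise ValueError(f"unknown stages: {sorted(unknown)}")
        for stage in STAGES:
            if stage in todo or _needed(stage, todo):
                getattr(self, f"stage_{stage}")()
        return self.res


def _needed(stage: str, todo: list[str]) -> bool:
    """A stage runs if any requested stage appears after it in the order."""
    order = list(STAGES)
    last = max(order.index(s) for s in todo)
    return order.index(stage) <= last


def run_pipeline(config, out_dir=None, stages=None) -> PipelineResult:
    """Run the pipeline from a PipelineConfig, dict, or YAML path."""
    if isinstance(config, (str, Path)):
        config = PipelineConfig.from_yaml(config)
    elif isinstance(config, dict):
        config = PipelineConfig.from_dict(config)
    return Pipeline(config, out_dir=out_dir).run(stages=stages)
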