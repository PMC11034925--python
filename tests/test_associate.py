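import itertools
import math

import numpy as np
import pandas as pd
import pytest

from cnekit.associate import (
    AssocParams,
    bootstrap_null,
    candidate_genes,
    classify_targets,
    select_targets,
    synteny_scores,
)
from cnekit.model import Interval, OrthologyTable, SpeciesGenome
from cnekit.search import Hit, PresenceMatrix

from conftest import random_dna


def mk_ortho(rows):
    df = pd.DataFrame(rows, columns=["species_id", "gene_id", "orthogroup_id", "paralog_partner_ids", "paralog_origin"])
    return OrthologyTable(df)


def mk_presence(hits):
    species = sorted({sp for _, sp in hits})
    pm = PresenceMatrix(species)
    for (cid, sp), loc in hits.items():
        pm.add_cne(cid, sp if sp == "A" else pm.ref_species.get(cid, "A"))
    pm2 = PresenceMatrix(species)
    for (cid, sp), loc in hits.items():
        pm2.add_cne(cid, "A")
        pm2.set_hit(cid, sp, Hit(cid, sp, loc, loc.strand, 100, 80, 1e-30, 0.9), 1)
    return pm2


class TestCandidateGenes:
    def _genomes(self, genes_by_sp, chrom_len=5_000_000):
        out = {}
        for sp, genes in genes_by_sp.items():
            out[sp] = SpeciesGenome(
                sequences={"chr1": "A" * chrom_len},
                genes={gid: iv for gid, iv in genes.items()},
            )
        return out

    def test_window_rule(self):
        genomes = self._genomes({"A": {
            "near": Interval("chr1", 1_500_000, 1_501_000),   # 500 kb away
            "far": Interval("chr1", 2_210_000, 2_211_000),    # 1.2 Mb away
        }})
        pm = mk_presence({("c", "A"): Interval("chr1", 1_000_000, 1_000_200)})
        cands = candidate_genes("c", pm, genomes, 1_000_000)
        assert [g for g, _ in cands["A"]] == ["near"]
        assert dict(cands["A"])["near"] == 499_800

    def test_intronic_gene_distance_zero(self):
        genomes = self._genomes({"A": {"host": Interval("chr1", 999_000, 1_002_000)}})
        pm = mk_presence({("c", "A"): Interval("chr1", 1_000_000, 1_000_200)})
        cands = candidate_genes("c", pm, genomes, 1_000_000)
        assert cands["A"] == [("host", 0)]

    def test_matches_brute_force_scan(self, rng):
        genes = {}
        for i in range(4):
            s = int(rng.integers(0, 4_000_000))
            genes[f"g{i}"] = Interval("chr1", s, s + 1_000)
        genomes = self._genomes({"A": genes})
        loc = Interval("chr1", 2_000_000, 2_000_300)
        pm = mk_presence({("c", "A"): loc})
        cands = candidate_genes("c", pm, genomes, 1_000_000).get("A", [])
        expected = []
        for gid, iv in genes.items():
            if iv.end > loc.start - 1_000_000 and iv.start < loc.end + 1_000_000:
                d = 0 if iv.overlaps(loc) else max(iv.start - loc.end, loc.start - iv.end)
                expected.append((gid, d))
        assert sorted(cands) == sorted(expected)


class TestSyntenyScores:
    def test_single_gene_all_species(self):
        ortho = mk_ortho([(sp, "g1", "OG1", "", "none") for sp in "abcdef"])
        cands = {sp: [("g1", 10_000)] for sp in "abcdef"}
        df = synteny_scores(cands, ortho)
        assert len(df) == 1
        assert df.iloc[0].synteny_score == 6 and df.iloc[0].proximity_rank == 1.0

    def test_fractional_rank_average(self):
        """Nearest in 3 species, second-nearest in 2 -> (1+1+1+2+2)/5 = 1.4."""
        rows = []
        for sp in "abcde":
            rows += [(sp, "t", "OGT", "", "none"), (sp, "o", "OGO", "", "none")]
        ortho = mk_ortho(rows)
        cands = {}
        for sp in "abc":
            cands[sp] = [("t", 100), ("o", 500)]
        for sp in "de":
            cands[sp] = [("o", 100), ("t", 500)]
        df = synteny_scores(cands, ortho).set_index("orthogroup")
        assert df.loc["OGT"].proximity_rank == pytest.approx(1.4)
        assert df.loc["OGT"].synteny_score == 5

    def test_distance_ties_share_rank(self):
        ortho = mk_ortho([("a", "x", "OGX", "", "none"), ("a", "y", "OGY", "", "none")])
        df = synteny_scores({"a": [("x", 100), ("y", 100)]}, ortho).set_index("orthogroup")
        assert df.loc["OGX"].proximity_rank == df.loc["OGY"].proximity_rank == 1.5

    def test_absent_orthogroup_excluded(self):
        ortho = mk_ortho([("a", "x", "OGX", "", "none")])
        df = synteny_scores({"a": [("x", 5)]}, ortho)
        assert set(df.orthogroup) == {"OGX"}


class TestSelectTargets:
    def _scored(self, rows):
        return pd.DataFrame(rows, columns=["orthogroup", "synteny_score", "proximity_rank"])

    def test_below_cutoff_gives_none(self):
        scored = self._scored([("OG1", 4, 1.0)])
        a = select_targets("c", scored, AssocParams(), "A", {}, mk_ortho([]))
        assert a.target_class == "none" and a.orthogroups == ()

    def test_ties_all_kept(self):
        scored = self._scored([("OG1", 6, 1.5), ("OG2", 6, 1.5), ("OG3", 6, 2.0)])
        a = select_targets("c", scored, AssocParams(), "A", {}, mk_ortho([]))
        assert a.orthogroups == ("OG1", "OG2") and a.synteny_score == 6

    def test_exhaustive_argmax_argmin(self, rng):
        for _ in range(30):
            rows = [(f"OG{i}", int(rng.integers(1, 9)), float(rng.integers(10, 40)) / 10) for i in range(3)]
            scored = self._scored(rows)
            a = select_targets("c", scored, AssocParams(min_synteny_species=5), "A", {}, mk_ortho([]))
            ok = [r for r in rows if r[1] >= 5]
            if not ok:
                assert a.orthogroups == ()
                continue
            smax = max(r[1] for r in ok)
            rmin = min(r[2] for r in ok if r[1] == smax)
            winners = sorted(r[0] for r in ok if r[1] == smax and r[2] == rmin)
            assert list(a.orthogroups) == winners


class TestClassify:
    def test_labels(self):
        from cnekit.associate import TargetAssociation

        a1 = TargetAssociation("c1", ("g",), ("OGdev",), 6, 1.0)
        a2 = TargetAssociation("c2", ("h",), ("OGother",), 6, 1.0)
        a3 = TargetAssociation("c3", (), (), 0, float("nan"))
        out = classify_targets({"c1": a1, "c2": a2, "c3": a3}, {"OGdev"})
        assert (a1.target_class, a2.target_class, a3.target_class) == ("ancestral", "novel", "none")


class TestBootstrapNull:
    def test_observed_equals_mean_z_zero(self):
        params = AssocParams(n_bootstrap=4_000, seed=1)
        genes = [f"g{i}" for i in range(10)]
        ogs = {g: ("OGA" if i < 5 else "OGB") for i, g in enumerate(genes)}
        res = bootstrap_null(0, [3] * 20, genes, ogs, {"OGA"}, params)
        res2 = bootstrap_null(int(round(res.mean)), [3] * 20, genes, ogs, {"OGA"}, params)
        assert abs(res2.z) < 0.2

    def test_tiny_case_matches_exhaustive_enumeration(self):
        """3 CNEs, 4 genes, 2 ancestral orthogroups: mean/sd of the null
        ancestral count match full enumeration of (subset, selection) draws."""
        genes = ["g1", "g2", "g3", "g4"]
        ogs = {"g1": "OGA", "g2": "OGA", "g3": "OGB", "g4": "OGC"}
        anc = {"OGA"}
        sizes = [2, 2, 2]
        # exhaustive: per CNE, draw a 2-subset uniformly, then pick a member
        # uniformly; P(ancestral) per CNE
        p_one = 0.0
        subsets = list(itertools.combinations(range(4), 2))
        for sub in subsets:
            for pick in sub:
                p_one += (1 / len(subsets)) * 0.5 * (ogs[genes[pick]] in anc)
        mean_exact = 3 * p_one
        sd_exact = math.sqrt(3 * p_one * (1 - p_one))
        params = AssocParams(n_bootstrap=10_000, seed=7)
        res = bootstrap_null(2, sizes, genes, ogs, anc, params)
        assert res.mean == pytest.approx(mean_exact, abs=0.03)
        assert res.sd == pytest.approx(sd_exact, abs=0.03)

    def test_deterministic_given_seed(self):
        genes = [f"g{i}" for i in range(20)]
        ogs = {g: "OGA" for g in genes[:8]} | {g: "OGB" for g in genes[8:]}
        params = AssocParams(n_bootstrap=2_000, seed=5)
        r1 = bootstrap_null(10, [4] * 15, genes, ogs, {"OGA"}, params)
        r2 = bootstrap_null(10, [4] * 15, genes, ogs, {"OGA"}, params)
        assert (r1.mean, r1.sd, r1.z) == (r2.mean, r2.sd, r2.z)

    def test_zero_sd_flagged_infinite(self):
        genes = ["g1"]
        res = bootstrap_null(5, [1] * 5, genes, {"g1": "OGA"}, {"OGA"}, AssocParams(n_bootstrap=50, seed=0))
        assert res.sd == 0.0 and res.infinite and math.isinf(res.z)
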