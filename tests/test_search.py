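import math

import numpy as np
import pytest
from Bio import Align

from cnekit._seqtools import revcomp
from cnekit.model import Interval, SpeciesGenome, GenomeSet
from cnekit.search import (
    GenomeIndex,
    SearchParams,
    build_presence_matrix,
    evalue,
    karlin_altschul_params,
    search,
    search_all,
)

from conftest import random_dna


class TestKarlinAltschul:
    def test_lambda_for_plus1_minus2(self):
        """Bisection oracle: 0.25 e^l + 0.75 e^(-2l) = 1 gives l ~= 1.3327."""
        lam, K = karlin_altschul_params(1, -2)
        assert lam == pytest.approx(1.3327057, abs=1e-5)
        # published ungapped blastn constant for +1/-2 is ~0.62
        assert K == pytest.approx(0.61, abs=0.05)

    def test_doubling_scores_halves_lambda(self):
        lam1, _ = karlin_altschul_params(1, -2)
        lam2, _ = karlin_altschul_params(2, -4)
        assert lam2 == pytest.approx(lam1 / 2, rel=1e-6)

    def test_lambda_decreases_with_weaker_mismatch(self):
        """Bisection at each penalty: lambda falls as mismatch weakens."""
        lams = [karlin_altschul_params(1, m)[0] for m in (-3.0, -2.5, -2.0, -1.5)]
        assert all(a > b for a, b in zip(lams, lams[1:]))

    def test_nonnegative_expected_score_rejected(self):
        with pytest.raises(ValueError):
            karlin_altschul_params(3, -0.5)

    def test_evalue_monotone_in_score(self):
        es = [evalue(s, 500, 10**6, 1, -2) for s in range(20, 200, 20)]
        assert all(a > b for a, b in zip(es, es[1:]))


def sw_best_score(query, genome, params):
    a = Align.PairwiseAligner()
    a.mode = "local"
    a.match_score = params.match
    a.mismatch_score = params.mismatch
    a.open_gap_score = params.gap_open + params.gap_extend
    a.extend_gap_score = params.gap_extend
    return max(a.score(query, genome), a.score(revcomp(query), genome))


class TestSearch:
    def test_exact_substring_hit(self, rng):
        genome = random_dna(rng, 50_000)
        q = genome[10_000:10_400]
        gidx = GenomeIndex({"chr1": genome}, SearchParams(), species_id="sp")
        (hit,) = search({"q": q}, gidx)
        assert hit.location == Interval("chr1", 10_000, 10_400)
        assert hit.identity == 1.0 and hit.evalue < 1e-50

    def test_random_query_no_hit(self, rng):
        genome = random_dna(rng, 1_000_000)
        gidx = GenomeIndex({"chr1": genome}, SearchParams(), species_id="sp")
        q = random_dna(rng, 100)
        hits = search({"q": q}, gidx)
        if hits:  # exhaustive confirmation that nothing above threshold exists
            sw = sw_best_score(q, genome, SearchParams())
            assert evalue(sw, 100, 1_000_000, 1, -2) <= 1e-6
        else:
            assert hits == []

    def test_revcomp_only_gives_minus_hit(self, rng):
        genome = random_dna(rng, 30_000)
        q = revcomp(genome[5_000:5_300])
        gidx = GenomeIndex({"chr1": genome}, SearchParams(), species_id="sp")
        (hit,) = search({"q": q}, gidx)
        assert hit.strand == "-" and hit.location.start == 5_000

    def test_best_hit_matches_smith_waterman(self, rng):
        """Best-hit scores agree with exhaustive Smith-Waterman on small
        genomes (50 randomized cases)."""
        params = SearchParams()
        n_checked = 0
        for case in range(50):
            glen = int(rng.integers(20_000, 50_000))
            genome = random_dna(rng, glen)
            qlen = int(rng.integers(150, 400))
            src = int(rng.integers(0, glen - qlen))
            div = rng.uniform(0.0, 0.25)
            q = "".join(c if rng.random() > div else "ACGT"[rng.integers(0, 4)] for c in genome[src : src + qlen])
            if rng.random() < 0.5:
                q = revcomp(q)
            gidx = GenomeIndex({"chr1": genome}, params, species_id="sp")
            hits = search({"q": q}, gidx, params)
            sw = sw_best_score(q, genome, params)
            if evalue(sw, qlen, glen, params.match, params.mismatch) <= params.evalue_max:
                assert hits, f"case {case}: SW finds a significant hit, search does not"
                assert hits[0].score == pytest.approx(sw, abs=2), f"case {case}"
                n_checked += 1
        assert n_checked >= 30

    def test_deterministic_and_batch_order_independent(self, rng):
        genome = random_dna(rng, 40_000)
        queries = {f"q{i}": genome[i * 1000 : i * 1000 + 300] for i in range(5)}
        gidx = GenomeIndex({"chr1": genome}, SearchParams(), species_id="sp")
        r1 = search_all(queries, gidx)
        r2 = search_all(dict(reversed(list(queries.items()))), gidx)
        for k in queries:
            assert [(h.location, h.score) for h in r1[k]] == [(h.location, h.score) for h in r2[k]]

    def test_repeat_masked_genome_not_searched(self, rng):
        genome = random_dna(rng, 20_000)
        q = genome[4_000:4_300]
        gidx = GenomeIndex({"chr1": genome}, SearchParams(), repeats=[Interval("chr1", 3_900, 4_400)], species_id="sp")
        assert search({"q": q}, gidx) == []


class _FakeSet:
    """Minimal CNE-set duck type for presence-matrix construction."""

    def __init__(self, ref_species, records):
        self.ref_species = ref_species
        self.records = records

    def sequences(self, genomes):
        g = genomes[self.ref_species]
        return {r.id: g.sequences[r.location.chrom][r.location.start : r.location.end] for r in self.records}


class TestPresenceMatrix:
    def test_reference_cell_uses_own_coordinates(self, rng):
        from cnekit.detect import CNERecord

        seq = random_dna(rng, 30_000)
        genomes = GenomeSet({
            "A": SpeciesGenome(sequences={"chr1": seq}),
            "B": SpeciesGenome(sequences={"chr1": seq[:15_000] + random_dna(rng, 15_000)}),
        })
        rec = CNERecord("c1", "A", Interval("chr1", 5_000, 5_400), ("A", "B"), 1.0, 400)
        pm = build_presence_matrix([_FakeSet("A", [rec])], genomes, SearchParams())
        assert pm.hit("c1", "A").location == rec.location
        assert pm.present("c1", "B")
        # round trip through the TSV form preserves presence and coordinates
        df = pm.to_frame()
        from cnekit.search import PresenceMatrix

        back = PresenceMatrix.from_frame(df)
        assert back.present("c1", "B") and back.hit("c1", "A").location.start == 5_000

    def test_absent_in_species_without_homolog(self, rng):
        from cnekit.detect import CNERecord

        genomes = GenomeSet({
            "A": SpeciesGenome(sequences={"chr1": random_dna(rng, 20_000)}),
            "B": SpeciesGenome(sequences={"chr1": random_dna(rng, 20_000)}),
        })
        rec = CNERecord("c1", "A", Interval("chr1", 2_000, 2_300), ("A", "B"), 1.0, 300)
        pm = build_presence_matrix([_FakeSet("A", [rec])], genomes, SearchParams())
        assert not pm.present("c1", "B")
        assert pm.present("c1", "A")
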