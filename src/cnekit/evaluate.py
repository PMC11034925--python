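"""Truth-based evaluation of pipeline output on simulated cohorts.

All metrics compare pipeline products with the simulator's ground truth:
base-pair detection recall/precision, ancestral-set recall, origin-category
accuracy, true-target selection accuracy, and presence-matrix fidelity.
"""

from __future__ import annotations

import logging
from collections import defaultdict

from .ancestry import AtCNESet
from .detect import CNESet
from .search import PresenceMatrix
from .simulate import CohortTruth

log = logging.getLogger(__name__)


def _interval_index(df):
    out = defaultdict(list)
    for row in df.itertuples():
        out[row.chrom].append((row.start, row.end, row.element_id))
    for ivs in out.values():
        ivs.sort()
    return out


def _covered_bp(ivs_a, ivs_b) -> tuple[int, int]:
    """(total bp of a, bp of a covered by b); both dicts chrom -> [(s, e, ...)]."""
    tot = cov = 0
    for chrom, ivs in ivs_a.items():
        others = ivs_b.get(chrom, [])
        for s, e, *_ in ivs:
            tot += e - s
            for bs, be, *_ in others:
                if be <= s:
                    continue
                if bs >= e:
                    break
                cov += min(e, be) - max(s, bs)
    return tot, cov


def bp_recall_precision(cnes: CNESet, truth: CohortTruth, species: str) -> tuple[float, float]:
    """Base-pair recall of planted elements and precision of detected bp."""
    tr = _interval_index(truth.elements_for(species))
    det = defaultdict(list)
    for r in cnes:
        det[r.location.chrom].append((r.location.start, r.location.end, r.id))
    for ivs in det.values():
        ivs.sort()
    tot_t, cov_t = _covered_bp(tr, det)
    tot_d, cov_d = _covered_bp(det, tr)
    recall = cov_t / tot_t if tot_t else float("nan")
    precision = cov_d / tot_d if tot_d else float("nan")
    return recall, precision


def truth_element_at(truth: CohortTruth, species: str, chrom: str, start: int, end: int):
    """Truth element row with the largest overlap with a detected location
    (>= half of the shorter span), or None."""
    best, best_ov = None, 0
    for row in truth.elements_for(species).itertuples():
        if row.chrom != chrom:
            continue
        ov = min(end, row.end) - max(start, row.start)
        if ov > best_ov:
            best, best_ov = row, ov
    if best is None:
        return None
    if best_ov < 0.5 * min(end - start, best.end - best.start):
        return None
    return best


def map_to_truth(atcnes_or_cnes, truth: CohortTruth) -> dict[str, object]:
    """cne_id -> matching truth row (detected elements without a truth match
    are absent from the mapping)."""
    out = {}
    for rec in atcnes_or_cnes:
        loc = rec.location
        row = truth_element_at(truth, rec.ref_species, loc.chrom, loc.start, loc.end)
        if row is not None:
            out[rec.id] = row
    return out


def expected_ancestral_ids(truth: CohortTruth, clade1, clade2) -> set[str]:
    """Planted elements retained in >= 1 species of each basal clade."""
    out = set()
    for eid in truth.elements.element_id.unique():
        sps = truth.species_with(eid)
        if sps & set(clade1) and sps & set(clade2):
            out.add(eid)
    return out


def atcne_recall(atcnes: AtCNESet, truth: CohortTruth, clade1, clade2) -> float:
    """Fraction of expected ancestral elements recovered in the atCNE set."""
    expected = expected_ancestral_ids(truth, clade1, clade2)
    if not expected:
        return float("nan")
    mapped = map_to_truth(atcnes, truth)
    recovered = {row.element_id for row in mapped.values()}
    return len(expected & recovered) / len(expected)


def category_accuracy(atcnes: AtCNESet, truth: CohortTruth) -> float:
    """Fraction of truth-matched atCNEs whose origin category equals the
    planted age class."""
    mapped = map_to_truth(atcnes, truth)
    n = ok = 0
    for m in atcnes:
        row = mapped.get(m.id)
        if row is None:
            continue
        n += 1
        if m.origin_category == row.age_class:
            ok += 1
    return ok / n if n else float("nan")


def target_accuracy(associations, atcnes: AtCNESet, truth: CohortTruth) -> float:
    """Fraction of associated, truth-matched elements whose selected target
    gene includes the planted true target."""
    mapped = map_to_truth(atcnes, truth)
    n = ok = 0
    for cid, assoc in associations.items():
        if assoc.target_class not in ("ancestral", "novel"):
            continue
        row = mapped.get(cid)
        if row is None or not row.target_gene:
            continue
        n += 1
        if row.target_gene in assoc.target_genes:
            ok += 1
    return ok / n if n else float("nan")


def presence_fidelity(presence: PresenceMatrix, cnes_by_id: dict, truth: CohortTruth, species: list[str]):
    """(recall, false_presence_rate) of the presence matrix vs truth.

    For each truth-matched query element and each non-reference species,
    truth presence (the ancestral element retained there) is compared with
    matrix presence.
    """
    tp = fn = fp = tn = 0
    for cid, row in cnes_by_id.items():
        # presence is homology-level: any retained copy of the ancestral
        # element counts, since the search reports the best hit genome-wide
        sub = truth.elements[truth.elements.ancestral_id == row.ancestral_id]
        truly_present = set(sub.species)
        ref_sp = row.species
        for sp in species:
            if sp == ref_sp:
                continue
            there = presence.present(cid, sp)
            if sp in truly_present:
                tp += there
                fn += not there
            else:
                fp += there
                tn += not there
    recall = tp / (tp + fn) if tp + fn else float("nan")
    false_rate = fp / (fp + tn) if fp + tn else float("nan")
    return recall, false_rate
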