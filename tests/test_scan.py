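"""PWM scanning and set-vs-genome z-score enrichment."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from promotif.motifs import build_weight_matrix
from promotif.promoters import PromoterRecord, PromoterUniverse
from promotif.scan import (
    MotifEnrichment,
    best_match,
    scan_universe,
    select_archetype,
    window_score,
    zscore_enrichment,
)
from promotif.simulate import high_information_pfm

from conftest import random_promoter
from oracles import brute_best_match, revcomp, window_score_loop


def test_window_score_matches_hand_summation(tiny_wm):
    rng = np.random.default_rng(5)
    for _ in range(20):
        w = "".join(rng.choice(list("ACGT"), size=tiny_wm.width))
        assert window_score(tiny_wm, w) == pytest.approx(
            window_score_loop(tiny_wm.weights.tolist(), w), abs=1e-12
        )


def test_window_score_consensus_and_anticonsensus(tiny_wm):
    consensus = tiny_wm.consensus()
    anti = "".join(
        "ACGT"[i] for i in np.argmin(tiny_wm.weights, axis=0)
    )
    assert window_score(tiny_wm, consensus) == pytest.approx(tiny_wm.max_score)
    assert window_score(tiny_wm, anti) == pytest.approx(tiny_wm.min_score)


def test_window_score_contract_violations(tiny_wm):
    with pytest.raises(ValueError, match="length"):
        window_score(tiny_wm, "ACGT")
    with pytest.raises(ValueError, match="N"):
        window_score(tiny_wm, "ANG")


def test_best_match_missing_when_promoter_too_short(gbox_wm):
    rec = PromoterRecord("short", "ACGT")
    assert best_match(gbox_wm, rec) is None


def test_best_match_all_n_promoter_is_missing(tiny_wm):
    assert best_match(tiny_wm, PromoterRecord("n", "N" * 30)) is None


def test_planted_consensus_in_poly_a_flank(gbox_wm):
    seq = "A" * 40 + gbox_wm.consensus() + "A" * 30
    hit = best_match(gbox_wm, PromoterRecord("planted", seq))
    assert hit.offset == 40
    assert hit.raw_score == pytest.approx(gbox_wm.max_score)
    assert hit.norm_score == pytest.approx(1.0)
    assert hit.strand == "+"


def test_best_match_equals_exhaustive_enumeration(tiny_wm, gbox_wm):
    rng = np.random.default_rng(17)
    for wm in (tiny_wm, gbox_wm):
        weights = wm.weights.tolist()
        for i in range(60):
            seq = random_promoter(rng, int(rng.integers(wm.width, 60)),
                                  with_n=True)
            hit = best_match(wm, PromoterRecord(f"r{i}", seq))
            oracle = brute_best_match(weights, seq)
            if oracle is None:
                assert hit is None
            else:
                score, off, strand = oracle
                assert hit.raw_score == pytest.approx(score, abs=1e-12)
                assert (hit.offset, hit.strand) == (off, strand)


_SYM_WM = build_weight_matrix(high_information_pfm("GCCACGTGGC", "SYM"))


@settings(deadline=None, max_examples=40, derandomize=True)
@given(st.text(alphabet="ACGT", min_size=12, max_size=50))
def test_strand_symmetry_of_best_score(seq):
    fwd = best_match(_SYM_WM, PromoterRecord("f", seq))
    rev = best_match(_SYM_WM, PromoterRecord("r", revcomp(seq)))
    assert fwd.raw_score == pytest.approx(rev.raw_score, abs=1e-9)


def test_adding_better_window_never_decreases_best(gbox_wm):
    rng = np.random.default_rng(23)
    base = random_promoter(rng, 60)
    before = best_match(gbox_wm, PromoterRecord("b", base)).raw_score
    improved = base[:10] + gbox_wm.consensus() + base[10 + gbox_wm.width:]
    after = best_match(gbox_wm, PromoterRecord("a", improved)).raw_score
    assert after >= before


def test_scan_universe_deterministic_and_in_range(small_universe, tiny_wm,
                                                  gbox_wm):
    t1 = scan_universe([tiny_wm, gbox_wm], small_universe)
    t2 = scan_universe([tiny_wm, gbox_wm], small_universe)
    assert t1.hits.to_csv() == t2.hits.to_csv()
    for wm in (tiny_wm, gbox_wm):
        raw = t1.motif_hits(wm.motif_id)["raw_score"]
        assert ((raw >= wm.min_score - 1e-12)
                & (raw <= wm.max_score + 1e-12)).all()
        norm = t1.motif_hits(wm.motif_id)["norm_score"]
        assert ((norm >= 0) & (norm <= 1)).all()


def test_scan_universe_missing_entries_for_unscoreable(gbox_wm):
    uni = PromoterUniverse.from_records(
        [PromoterRecord(f"s{i}", "ACGT") for i in range(3)]
    )
    table = scan_universe([gbox_wm], uni)
    assert len(table.hits) == 0
    assert table.n_universe == 3


def test_norm_score_invariant_under_affine_weight_rescale(tiny_pfm):
    """norm = (raw-min)/(max-min) is unchanged by a*W + per-column shifts."""
    wm = build_weight_matrix(tiny_pfm, pseudocount=1.0)
    rng = np.random.default_rng(29)
    seq = random_promoter(rng, 40)
    scaled = build_weight_matrix(tiny_pfm, pseudocount=1.0)
    shifts = rng.normal(size=wm.width)
    scaled.weights = 3.0 * wm.weights + shifts  # affine per-column transform
    scaled.min_score = float(scaled.weights.min(axis=0).sum())
    scaled.max_score = float(scaled.weights.max(axis=0).sum())
    h1 = best_match(wm, PromoterRecord("x", seq))
    h2 = best_match(scaled, PromoterRecord("x", seq))
    assert h1.norm_score == pytest.approx(h2.norm_score, abs=1e-9)
    assert (h1.offset, h1.strand) == (h2.offset, h2.strand)


# ---- z-score enrichment ---------------------------------------------------


def _table_for(universe, wms):
    return scan_universe(wms, universe)


def test_whole_universe_set_gives_z_zero(small_universe, tiny_wm):
    table = _table_for(small_universe, [tiny_wm])
    (enr,) = zscore_enrichment(
        table, set(small_universe.gene_ids), "all"
    )
    assert enr.z == pytest.approx(0.0, abs=1e-9)
    assert enr.p == pytest.approx(0.5, abs=1e-9)


def test_zscore_matches_hand_arithmetic(small_universe, tiny_wm):
    table = _table_for(small_universe, [tiny_wm])
    genes = small_universe.gene_ids[:5]
    (enr,) = zscore_enrichment(table, set(genes), "hand")
    scores = table.norm_scores(tiny_wm.motif_id)
    pop = scores.to_numpy()
    mean_set = scores.loc[genes].mean()
    z_hand = (mean_set - pop.mean()) / (pop.std() / math.sqrt(5))
    assert enr.z == pytest.approx(z_hand, abs=1e-12)
    assert enr.n_set == 5
    # one-sided upper tail: p decreases as z increases
    from scipy.stats import norm

    assert enr.p == pytest.approx(norm.sf(z_hand), rel=1e-12)


def test_zscore_errors_on_degenerate_inputs(tiny_wm):
    uni = PromoterUniverse.from_records(
        [PromoterRecord(f"c{i}", "AAAAAAAA") for i in range(5)]
    )
    table = scan_universe([tiny_wm], uni)
    with pytest.raises(ValueError, match="sd"):
        zscore_enrichment(table, {"c0", "c1"}, "x")


def test_zscore_requires_two_scored_genes(small_universe, tiny_wm):
    table = _table_for(small_universe, [tiny_wm])
    with pytest.raises(ValueError, match="fewer than 2"):
        zscore_enrichment(table, {"g0"}, "solo")


def test_bh_adjustment_across_motifs(small_universe, tiny_wm, gbox_wm):
    table = _table_for(small_universe, [tiny_wm, gbox_wm])
    enr = zscore_enrichment(table, set(small_universe.gene_ids[:6]), "s")
    ps = sorted(e.p for e in enr)
    adj = sorted(e.p_adjusted for e in enr)
    assert adj[-1] >= ps[-1] - 1e-15
    assert all(0 < a <= 1 for a in adj)


# ---- archetype selection --------------------------------------------------


def _enr(motif_id, p, z=1.0):
    return MotifEnrichment(
        motif_id=motif_id, set_name="s", n_set=5, mean_set=0.5,
        mean_pop=0.4, sd_pop=0.1, z=z, p=p, p_adjusted=p,
    )


def test_archetype_single_motif_per_family():
    chosen = select_archetype([_enr("M1", 0.01)], {"M1": "G-box"})
    assert chosen == {"G-box": "M1"}


def test_archetype_picks_smallest_p():
    enrs = [_enr("M1", 1e-3), _enr("M2", 1e-6)]
    chosen = select_archetype(enrs, {"M1": "G-box", "M2": "G-box"})
    assert chosen == {"G-box": "M2"}


def test_archetype_tie_breaks_lexicographically(caplog):
    import logging

    enrs = [_enr("M2", 1e-4), _enr("M1", 1e-4)]
    with caplog.at_level(logging.WARNING, logger="promotif.scan"):
        chosen = select_archetype(enrs, {"M1": "F", "M2": "F"})
    assert chosen == {"F": "M1"}
    assert any("tie" in r.message for r in caplog.records)


def test_archetype_missing_family_errors():
    with pytest.raises(ValueError, match="W-box"):
        select_archetype([_enr("M1", 0.01)], {"M1": "G-box", "M9": "W-box"})
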