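"""SNR-based call refinement, rank-sum test and redundant-probe consolidation."""
import itertools

import numpy as np
import pytest

import mitofilter as mf
from mitofilter.model import PositionRecord, StrandSignal


def _rec(sense, anti, quality=30.0, hap="A", dip=None, position=10, probe_set=0):
    return PositionRecord(
        position=position,
        probe_set_id=probe_set,
        sense=StrandSignal(*sense),
        antisense=StrandSignal(*anti),
        quality=quality,
        haploid_call=hap,
        diploid_call=dip if dip is not None else hap,
    )


# ---------------------------------------------------------------------------
# combined SNR
# ---------------------------------------------------------------------------

def test_combined_snr_takes_min_over_strands():
    ratio, top = mf.combined_snr(_rec((1000, 50, 40, 30), (900, 60, 45, 20)))
    assert top == "A"
    assert ratio == pytest.approx(15.0)  # min(1000/50, 900/60)


def test_combined_snr_tied_top_two_never_rescues():
    ratio, top = mf.combined_snr(_rec((500, 500, 50, 50), (600, 100, 50, 50)))
    assert ratio == pytest.approx(1.0)
    assert ratio <= 1.26


def test_combined_snr_strand_disagreement_gives_no_top_base():
    ratio, top = mf.combined_snr(_rec((1000, 50, 40, 30), (60, 900, 45, 20)))
    assert top is None
    assert ratio == pytest.approx(min(1000 / 50, 900 / 60))


# ---------------------------------------------------------------------------
# SNR threshold from noise ratios
# ---------------------------------------------------------------------------

def test_snr_threshold_zero_spread():
    assert mf.snr_threshold_from_noise([1.0, 1.0, 1.0, 1.0]) == pytest.approx(1.0)


def test_snr_threshold_brute_force_eight_values():
    ratios = [1.0, 1.0, 1.1, 1.1, 1.2, 1.2, 1.3, 1.3]
    q1, q3 = np.percentile(ratios, [25, 75])
    inner = [r for r in ratios if q1 <= r <= q3]
    expected = np.median(ratios) + 4 * np.std(inner, ddof=1)
    assert inner == [1.1, 1.1, 1.2, 1.2]
    assert mf.snr_threshold_from_noise(ratios) == pytest.approx(expected)
    assert expected == pytest.approx(1.15 + 4 * np.sqrt(0.01 / 3))


def test_snr_threshold_needs_four_values():
    with pytest.raises(mf.ValidationError):
        mf.snr_threshold_from_noise([1.0, 1.1, 1.2])


# ---------------------------------------------------------------------------
# refinement
# ---------------------------------------------------------------------------

def _one_position_sample(layout, records):
    """Sample whose primary block is synthesised from per-position records."""
    pos = layout.interrogable_positions
    n = len(pos)
    sense = np.full((n, 4), 50.0)
    sense[:, 0] = 1050.0
    anti = sense.copy()
    q = np.full(n, 30.0)
    hap = np.full(n, "A", dtype="<U1")
    dip = hap.copy()
    block = mf.ProbeBlock(0, pos, sense, anti, q, hap, dip)
    sample = mf.SampleDataset("s", {0: block})
    for rec in records:
        i = block.index_of(rec.position)
        block.sense[i] = rec.sense.as_array()
        block.antisense[i] = rec.antisense.as_array()
        block.quality[i] = rec.quality
        block.haploid_call[i] = rec.haploid_call
        block.diploid_call[i] = rec.diploid_call
    return sample


def test_refine_calls_contract_cases(small_layout):
    ref = "A" * small_layout.genome_length
    records = [
        # reference-matching, good quality: untouched
        _rec((1050, 50, 50, 50), (1050, 50, 50, 50), quality=40, hap="A", position=10),
        # N with SNR 2.0 and strand-consistent top base: rescued
        _rec((200, 100, 50, 50), (220, 100, 50, 50), quality=1.0, hap="N", position=20),
        # variant with quality 10 and high SNR: demoted on quality
        _rec((50, 1050, 50, 50), (50, 1050, 50, 50), quality=10, hap="C", position=30),
        # variant with quality 30 but SNR below threshold: demoted on SNR
        _rec((50, 520, 500, 50), (50, 530, 500, 50), quality=30, hap="C", position=40),
        # low-quality position that stays N (SNR 1.0)
        _rec((50, 50, 50, 50), (50, 50, 50, 50), quality=1.0, hap="N", position=50),
    ]
    sample = _one_position_sample(small_layout, records)
    track = mf.refine_calls(sample, ref)
    at = {p: track.index_of(p) for p in (10, 20, 30, 40, 50)}
    assert track.final_call[at[10]] == "A"
    assert track.provenance[at[10]] == "primary"
    assert track.final_call[at[20]] == "A"
    assert track.provenance[at[20]] == "rescued"
    assert track.final_call[at[30]] == "N"
    assert track.provenance[at[30]] == "demoted_quality"
    assert track.final_call[at[40]] == "N"
    assert track.provenance[at[40]] == "demoted_snr"
    assert track.final_call[at[50]] == "N"


def test_refine_never_touches_reference_matching_calls(small_layout, small_reference):
    cfg = mf.GeneratorConfig(
        seed=40, n_samples=1, layout=small_layout, reference=small_reference
    )
    batch, _ = mf.generate_batch(cfg)
    sample = batch.samples[0]
    track = mf.refine_calls(sample, small_reference)
    block = sample.primary
    ref = np.array(list(small_reference))[block.positions - 1]
    matching = (block.haploid_call == ref) & (block.quality >= 3.0)
    np.testing.assert_array_equal(track.final_call[matching], block.haploid_call[matching])


def test_refine_is_idempotent_with_provenance_passthrough(small_layout):
    ref = "A" * small_layout.genome_length
    records = [
        _rec((200, 100, 50, 50), (220, 100, 50, 50), quality=1.0, hap="N", position=20),
        _rec((50, 1050, 50, 50), (50, 1050, 50, 50), quality=10, hap="C", position=30),
        _rec((50, 520, 500, 50), (50, 530, 500, 50), quality=30, hap="C", position=40),
    ]
    sample = _one_position_sample(small_layout, records)
    track1 = mf.refine_calls(sample, ref)
    # feed the final calls back through as haploid calls
    sample2 = sample.copy()
    sample2.primary.haploid_call[:] = track1.final_call
    track2 = mf.refine_calls(sample2, ref, prior=track1)
    np.testing.assert_array_equal(track1.final_call, track2.final_call)
    np.testing.assert_array_equal(track1.provenance, track2.provenance)


def test_noise_free_parameter_recovery(noise_free_batch):
    batch, truth = noise_free_batch
    for sample in batch.samples:
        track = mf.refine_calls(sample, batch.reference)
        assert mf.call_rate(track, batch.layout) == 1.0
        _, variants = mf.consensus_and_variants(track, batch.reference)
        assert {(v.position, v.alt) for v in variants} == set(
            truth.variants[sample.sample_id]
        )


# ---------------------------------------------------------------------------
# rank-sum test
# ---------------------------------------------------------------------------

def _oracle_rank_sum(xs, ys):
    """Independent exact oracle via the Mann-Whitney U count statistic,
    enumerated over all group assignments of the pooled values."""
    pooled = list(xs) + list(ys)
    n = len(xs)

    def u_stat(group_a, group_b):
        u = 0.0
        for a in group_a:
            for b in group_b:
                u += 1.0 if a > b else 0.5 if a == b else 0.0
        return u

    mu = len(xs) * len(ys) / 2.0
    dev = abs(u_stat(xs, ys) - mu)
    hits = total = 0
    for combo in itertools.combinations(range(len(pooled)), n):
        ga = [pooled[i] for i in combo]
        gb = [pooled[i] for i in range(len(pooled)) if i not in set(combo)]
        total += 1
        if abs(u_stat(ga, gb) - mu) >= dev - 1e-9:
            hits += 1
    return hits / total


def test_rank_sum_identical_groups_p_one():
    assert mf.rank_sum_p([1, 2, 3], [1, 2, 3]) == pytest.approx(1.0)


@pytest.mark.parametrize(
    "xs,ys,expected",
    [([1, 2, 3], [4, 5, 6], 2 / 20), ([1, 2, 3, 4], [5, 6, 7, 8], 2 / 70)],
)
def test_rank_sum_exact_hand_enumerated(xs, ys, expected):
    assert mf.rank_sum_p(xs, ys) == pytest.approx(expected)


def test_rank_sum_exact_matches_independent_oracle_small_groups():
    rng = np.random.default_rng(7)
    for _ in range(60):
        n, m = rng.integers(1, 6), rng.integers(1, 6)
        xs = rng.integers(0, 6, n).astype(float)  # integer values force ties
        ys = rng.integers(0, 6, m).astype(float)
        assert mf.rank_sum_p(xs, ys) == pytest.approx(_oracle_rank_sum(xs, ys))


def test_rank_sum_normal_approximation_close_to_exact():
    rng = np.random.default_rng(8)
    for _ in range(20):
        xs = rng.normal(0, 1, 8)
        ys = rng.normal(0.3, 1, 8)
        exact = mf.rank_sum_p(xs, ys, method="exact")
        approx = mf.rank_sum_p(xs, ys, method="normal")
        assert abs(exact - approx) <= 0.02


def test_rank_sum_rejects_empty_group():
    with pytest.raises(mf.ValidationError):
        mf.rank_sum_p([], [1.0])


# ---------------------------------------------------------------------------
# consolidation
# ---------------------------------------------------------------------------

def _vote(hap, quality, probe_set):
    return _rec(
        (1050, 50, 50, 50), (1050, 50, 50, 50),
        quality=quality, hap=hap, position=10, probe_set=probe_set,
    )


def test_consolidation_unanimous_vote():
    records = [_vote("A", q, i) for i, q in enumerate([30, 28, 25, 20])]
    assert mf.consolidate_redundant(records) == ("A", False)


def test_consolidation_two_vs_two_tie_is_flagged():
    # exact rank-sum on 2v2 cannot reach p < 0.05, so the tie stands
    records = [
        _vote("A", 30, 0), _vote("A", 28, 1), _vote("G", 5, 2), _vote("G", 4, 3),
    ]
    assert mf.rank_sum_p([30, 28], [5, 4]) == pytest.approx(2 / 6)
    assert mf.consolidate_redundant(records) == ("N", True)


def test_consolidation_four_vs_four_resolves_to_higher_quality_group():
    records = [_vote("A", q, i) for i, q in enumerate([30, 29, 28, 27])]
    records += [_vote("G", q, i + 4) for i, q in enumerate([5, 4, 3.5, 3.2])]
    assert mf.rank_sum_p([30, 29, 28, 27], [5, 4, 3.5, 3.2]) == pytest.approx(2 / 70)
    assert mf.consolidate_redundant(records) == ("A", False)


def test_consolidation_excludes_low_quality_and_n_votes():
    records = [
        _vote("A", 30, 0),
        _vote("G", 2.5, 1),  # below the call floor: no vote
        _vote("N", 30, 2),   # N never votes
    ]
    assert mf.consolidate_redundant(records) == ("A", False)
    assert mf.consolidate_redundant([_vote("N", 30, 0)]) == ("N", False)


def test_consolidation_is_order_invariant():
    records = [_vote("A", 30, 0), _vote("A", 28, 1), _vote("G", 25, 2), _vote("G", 26, 3)]
    base = mf.consolidate_redundant(records)
    for perm in itertools.permutations(records):
        assert mf.consolidate_redundant(list(perm)) == base


def test_consolidation_rejects_mixed_positions():
    records = [_vote("A", 30, 0), _rec((1050, 50, 50, 50), (1050, 50, 50, 50), position=11)]
    with pytest.raises(mf.ValidationError):
        mf.consolidate_redundant(records)


# ---------------------------------------------------------------------------
# consensus and variants
# ---------------------------------------------------------------------------

def test_consensus_identical_to_reference_has_no_variants(small_layout, small_reference):
    cfg = mf.GeneratorConfig(
        seed=41, n_samples=1, layout=small_layout, reference=small_reference,
        intensity_noise_sd=0.0, q_clean_sd=0.0,
    )
    batch, _ = mf.generate_batch(cfg)
    track = mf.refine_calls(batch.samples[0], small_reference)
    consensus, variants = mf.consensus_and_variants(track, small_reference)
    assert variants == []
    called = [consensus.sequence[p - 1] for p in small_layout.interrogable_positions]
    assert called == [small_reference[p - 1] for p in small_layout.interrogable_positions]


def test_single_variant_reported_at_its_position():
    layout = mf.ArrayLayout.default()
    ref = ("ACGT" * 4143)[:16569]
    alt = "G" if ref[3242] != "G" else "A"
    spec = mf.SampleSpec("s", variants=[(3243, alt)])
    cfg = mf.GeneratorConfig(
        seed=42, samples=[spec], reference=ref,
        intensity_noise_sd=0.0, q_clean_sd=0.0,
    )
    batch, _ = mf.generate_batch(cfg)
    track = mf.refine_calls(batch.samples[0], ref)
    _, variants = mf.consensus_and_variants(track, ref)
    assert [(v.position, v.ref, v.alt) for v in variants] == [(3243, ref[3242], alt)]
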