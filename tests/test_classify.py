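import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from phage_termini import (
    HybridEvidence,
    PackagingCall,
    ReferenceGenome,
    Thresholds,
    classify_from_peaks,
    classify_mu_or_headful,
    compute_tau,
    detect_hybrid_fragments,
    estimate_concatemer_copies,
    extract_junction_sequence,
    transduction_metrics,
)
from phage_termini.classify import ConfigError
from phage_termini.coverage import PeakCall, StrandProfiles

from conftest import random_genome

G = 60_000


def peak(position, strand, tau, spc=1000):
    return PeakCall(position=position, strand=strand, tau=tau, SPC_merged=spc,
                    pvalue=1e-30, adjusted_pvalue=1e-20, members=[position])


@pytest.fixture(scope="module")
def flat_profiles():
    prof = StrandProfiles(
        SPC_fwd=np.ones(G, dtype=np.int64),
        SPC_rev=np.ones(G, dtype=np.int64),
        COV_fwd=np.full(G, 50, dtype=np.int64),
        COV_rev=np.full(G, 50, dtype=np.int64),
        FCOV=np.full(G, 100, dtype=np.int64),
        G=G,
    )
    return prof


@pytest.fixture(scope="module")
def flat_tau(flat_profiles):
    return compute_tau(flat_profiles, paired=True, F=400.0)


def classify(fwd, rev, profiles, tau):
    return classify_from_peaks(fwd, rev, tau, profiles, G)


class TestPeakRules:
    def test_cos_5p_forward_left_of_reverse(self, flat_profiles, flat_tau):
        # Lambda-like: termini 11 bp apart, forward left of reverse
        call = classify([peak(10867, "forward", 0.59)],
                        [peak(10878, "reverse", 0.41)],
                        flat_profiles, flat_tau)
        assert call.phage_class == "COS_5p"
        assert (call.left_terminus, call.right_terminus) == (10868, 10879)
        assert call.termini_redundancy == "non_redundant"

    def test_cos_3p_forward_right_of_reverse(self, flat_profiles, flat_tau):
        call = classify([peak(2046, "forward", 0.51)],
                        [peak(2035, "reverse", 0.60)],
                        flat_profiles, flat_tau)
        assert call.phage_class == "COS_3p"
        assert (call.left_terminus, call.right_terminus) == (2047, 2036)

    def test_dtr_needs_doubled_interpeak_coverage(self, flat_profiles, flat_tau):
        prof = StrandProfiles(
            SPC_fwd=flat_profiles.SPC_fwd.copy(),
            SPC_rev=flat_profiles.SPC_rev.copy(),
            COV_fwd=flat_profiles.COV_fwd.copy(),
            COV_rev=flat_profiles.COV_rev.copy(),
            FCOV=flat_profiles.FCOV.copy(),
            G=G,
        )
        prof.FCOV[7739:7899] *= 2  # the repeat is covered twice
        call = classify([peak(7739, "forward", 0.47)],
                        [peak(7898, "reverse", 0.51)],
                        prof, flat_tau)
        assert call.phage_class == "DTR_short"
        assert (call.left_terminus, call.right_terminus) == (7740, 7899)
        assert call.termini_redundancy == "redundant"

    def test_distant_peaks_without_coverage_gain_defer(self, flat_profiles, flat_tau):
        call = classify([peak(7739, "forward", 0.47)],
                        [peak(7898, "reverse", 0.51)],
                        flat_profiles, flat_tau)
        assert call is None

    def test_long_repeat_subtype(self, flat_profiles, flat_tau):
        prof = StrandProfiles(
            SPC_fwd=flat_profiles.SPC_fwd, SPC_rev=flat_profiles.SPC_rev,
            COV_fwd=flat_profiles.COV_fwd, COV_rev=flat_profiles.COV_rev,
            FCOV=flat_profiles.FCOV.copy(), G=G,
        )
        prof.FCOV[1000:12000] *= 2
        call = classify([peak(1000, "forward", 0.5)],
                        [peak(11999, "reverse", 0.5)],
                        prof, flat_tau)
        assert call.phage_class == "DTR_long"

    def test_single_strand_peak_is_pac(self, flat_profiles, flat_tau):
        call = classify([peak(54884, "forward", 0.20)], [],
                        flat_profiles, flat_tau)
        assert call.phage_class == "HEADFUL_PAC"
        assert call.packaging_orientation == "forward"
        assert call.left_terminus == 54885 and call.right_terminus is None

    def test_two_weak_peaks_same_strand_is_multiple(self, flat_profiles, flat_tau):
        call = classify([peak(100, "forward", 0.25), peak(9000, "forward", 0.22)],
                        [], flat_profiles, flat_tau)
        assert call.phage_class == "MULTIPLE"

    def test_strong_peak_suppresses_multiple(self, flat_profiles, flat_tau):
        call = classify([peak(100, "forward", 0.55), peak(9000, "forward", 0.15)],
                        [], flat_profiles, flat_tau)
        assert call.phage_class != "MULTIPLE"

    def test_low_tau_peaks_are_ignored(self, flat_profiles, flat_tau):
        assert classify([peak(100, "forward", 0.05)],
                        [peak(500, "reverse", 0.08)],
                        flat_profiles, flat_tau) is None

    def test_weak_cos_call_carries_contamination_note(self, flat_profiles, flat_tau):
        call = classify([peak(1000, "forward", 0.20)],
                        [peak(1005, "reverse", 0.18)],
                        flat_profiles, flat_tau)
        assert call.phage_class == "COS_5p"
        assert any("contaminated" in n for n in call.notes)

    def test_contradictory_thresholds_rejected(self, flat_profiles, flat_tau):
        bad = Thresholds(cos_max_distance=2000, dtr_long_min=1000)
        with pytest.raises(ConfigError):
            classify_from_peaks([], [], flat_tau, flat_profiles, G, bad)


@settings(max_examples=200, derandomize=True)
@given(
    st.lists(
        st.tuples(
            st.integers(0, G - 1),
            st.sampled_from(["forward", "reverse"]),
            st.floats(0.0, 1.0),
        ),
        max_size=6,
    ),
    st.floats(0.0, 0.1),
)
def test_every_peak_configuration_maps_to_exactly_one_class(entries, observed):
    """Decision completeness: any peak table plus any hybrid evidence yields
    exactly one packaging class without error."""
    prof = StrandProfiles(
        SPC_fwd=np.ones(G, dtype=np.int64), SPC_rev=np.ones(G, dtype=np.int64),
        COV_fwd=np.full(G, 50, dtype=np.int64), COV_rev=np.full(G, 50, dtype=np.int64),
        FCOV=np.full(G, 100, dtype=np.int64), G=G,
    )
    tau = compute_tau(prof, paired=True, F=400.0)
    seen = set()
    fwd = []
    rev = []
    for pos, strand, t in entries:
        if (pos, strand) in seen:
            continue
        seen.add((pos, strand))
        (fwd if strand == "forward" else rev).append(peak(pos, strand, t))
    call = classify_from_peaks(fwd, rev, tau, prof, G)
    if call is None:
        evidence = HybridEvidence(
            hybrid_count=int(observed * 1000), total_phage_fragments=1000,
            observed_proportion=observed, expected_proportion=0.025,
        )
        call = classify_mu_or_headful(evidence, G)
    assert call.phage_class in (
        "COS_5p", "COS_3p", "DTR_short", "DTR_long", "HEADFUL_PAC",
        "HEADFUL", "MU_LIKE", "MULTIPLE", "UNKNOWN",
    )


class TestHybridFragments:
    def test_closed_form_expectation(self):
        phage = ReferenceGenome("p", random_genome(np.random.default_rng(0), 36_000))
        host = ReferenceGenome("h", random_genome(np.random.default_rng(1), 5_000))
        ev = detect_hybrid_fragments([], phage, host, seed_length=20, F=485.0)
        assert ev.expected_proportion == pytest.approx(2 * (485 - 40) / 36_000)
        assert ev.expected_proportion == pytest.approx(0.02472, abs=1e-4)
        assert ev.observed_proportion == 0.0

    def test_missing_host_is_an_error(self):
        phage = ReferenceGenome("p", "ACGT" * 100)
        with pytest.raises(ValueError, match="host"):
            detect_hybrid_fragments([], phage, None, seed_length=20, F=400.0)

    @pytest.mark.parametrize(
        "observed,expected_class",
        [
            (0.020, "MU_LIKE"),   # Mu-like: at least half the expectation
            (0.0125, "MU_LIKE"),  # exactly half
            (0.010, "HEADFUL"),   # hybrids present but too few
            (0.0, "UNKNOWN"),     # no hybrids at all
        ],
    )
    def test_mu_decision_boundaries(self, observed, expected_class):
        ev = HybridEvidence(
            hybrid_count=int(observed * 10_000), total_phage_fragments=10_000,
            observed_proportion=observed, expected_proportion=0.025,
        )
        call = classify_mu_or_headful(ev, G=36_000)
        assert call.phage_class == expected_class

    def test_unassessable_expectation_is_an_error(self):
        ev = HybridEvidence(0, 0, 0.0, expected_proportion=0.0)
        with pytest.raises(ValueError):
            classify_mu_or_headful(ev, G=36_000)


class TestConcatemerEstimate:
    def test_tau_form(self):
        assert estimate_concatemer_copies(tau=0.2).from_tau == pytest.approx(4.0)
        assert estimate_concatemer_copies(tau=0.5).from_tau == pytest.approx(1.0)

    def test_peak_size_form(self):
        # F * R/T - 1 with T/R = 101, F = 494 gives C ~ 3.9
        est = estimate_concatemer_copies(T=101.0, R=1.0, F=494.0)
        assert est.from_peak_size == pytest.approx(3.89, abs=0.01)

    def test_both_forms_average(self):
        est = estimate_concatemer_copies(tau=0.2, T=100.0, R=1.0, F=500.0)
        assert est.mean == pytest.approx(4.0)

    def test_tau_of_one_is_not_pac(self):
        with pytest.raises(ValueError):
            estimate_concatemer_copies(tau=1.0)

    def test_negative_estimate_dropped(self):
        est = estimate_concatemer_copies(T=1000.0, R=1.0, F=500.0)
        assert est.from_peak_size is None and est.mean is None


@pytest.fixture(scope="module")
def junction_ref():
    return ReferenceGenome("p", random_genome(np.random.default_rng(2), 10_000))


class TestJunctionExtraction:
    @pytest.fixture
    def ref(self, junction_ref):
        return junction_ref

    def test_cos5_overhang_inclusive_span(self, ref):
        call = PackagingCall("COS_5p", left_terminus=101, right_terminus=112)
        extract_junction_sequence(call, ref)
        assert call.junction_sequence == ref.sequence[100:112]
        assert len(call.junction_sequence) == 12

    def test_cos3_gap_sequence(self, ref):
        call = PackagingCall("COS_3p", left_terminus=67, right_terminus=55)
        extract_junction_sequence(call, ref)
        assert len(call.junction_sequence) == 13
        assert call.junction_sequence == ref.sequence[54:67]

    def test_dtr_repeat_length(self, ref):
        call = PackagingCall("DTR_short", left_terminus=7740 % 10_000,
                             right_terminus=7740 % 10_000 + 159)
        extract_junction_sequence(call, ref)
        assert len(call.junction_sequence) == 160

    def test_out_of_bounds_terminus_is_an_error(self, ref):
        call = PackagingCall("DTR_short", left_terminus=9990, right_terminus=10_500)
        with pytest.raises(ValueError):
            extract_junction_sequence(call, ref)

    def test_classes_without_junction_rejected(self, ref):
        with pytest.raises(ValueError):
            extract_junction_sequence(PackagingCall("HEADFUL_PAC"), ref)


class TestTransduction:
    def test_no_host_reads_gives_zero_fraction(self):
        host = ReferenceGenome("h", random_genome(np.random.default_rng(3), 20_000))
        ev = HybridEvidence(0, 100, 0.0, 0.025, total_reads=1000)
        out = transduction_metrics(ev, host)
        assert out["host_read_fraction"] == 0.0
        assert out["attachment_site"] is None

    def test_clustered_hybrid_positions_flag_attachment_site(self):
        host = ReferenceGenome("h", random_genome(np.random.default_rng(4), 50_000))
        rng = np.random.default_rng(5)
        positions = list(rng.integers(0, 50_000, 30)) + [25_100 + int(x) for x in rng.integers(0, 400, 60)]
        ev = HybridEvidence(90, 1000, 0.09, 0.025, host_positions=positions,
                            host_only_reads=40, total_reads=1000)
        out = transduction_metrics(ev, host)
        assert out["host_read_fraction"] == pytest.approx(0.04)
        assert out["attachment_site"] is not None
        assert abs(out["attachment_site"] - 25_300) < 1000
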