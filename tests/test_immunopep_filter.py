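import itertools
import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from erv_antigen.immunopep_filter import (
    PsmRecord,
    apply_fixed_thresholds,
    binder_category,
    estimate_fdr_threshold,
    finalize_peptide_calls,
    hamming_distance,
    label_shift,
    peptide_monoisotopic_mass,
    read_psm_tsv,
    select_rt_calibration,
    sequence_tag_length,
    spectral_angle,
    strike_classify,
    write_psm_tsv,
)
from erv_antigen.sixframe_db import OrfProtein, build_search_db, map_peptide_sources


def make_psm(psm_id, score, decoy=False, **kw):
    defaults = dict(
        peptide="LLDPKTGSW", charge=2, sm_score=score, spi_pct=75.0, bcs=8.0,
        rt_obs_min=30.0, rt_pred_min=30.0, hla_rank=0.5, is_decoy=decoy,
        run_id="run1", source_class="erv",
    )
    defaults.update(kw)
    return PsmRecord(psm_id=psm_id, **defaults)


class TestFdr:
    def test_no_decoys_accepts_everything_with_warning(self):
        psms = [make_psm(f"p{i}", 5 + i) for i in range(100)]
        with pytest.warns(UserWarning, match="no decoy"):
            res = estimate_fdr_threshold(psms, 0.01)
        assert len(res.accepted) == 100
        assert all(q == 0.0 for q in res.qvalues.values())

    def test_hand_evaluated_example(self):
        # targets at {10, 9, 8}, one decoy at 8: FDR(9) = 0/2 -> cutoff 9
        psms = [
            make_psm("t10", 10), make_psm("t9", 9), make_psm("t8", 8),
            make_psm("d8", 8, decoy=True),
        ]
        res = estimate_fdr_threshold(psms, 0.01)
        assert res.cutoffs["aggregate"] == 9
        assert {p.psm_id for p in res.accepted} == {"t10", "t9"}

    def test_qvalues_non_increasing_in_score(self):
        rng = np.random.default_rng(0)
        psms = [
            make_psm(f"p{i}", float(rng.normal(8, 3)), decoy=bool(rng.integers(2)))
            for i in range(500)
        ]
        res = estimate_fdr_threshold(psms, 0.05)
        ordered = sorted(psms, key=lambda p: -p.sm_score)
        qs = [res.qvalues[p.psm_id] for p in ordered]
        assert all(a <= b for a, b in zip(qs, qs[1:]))

    def test_accepted_sets_nested_across_levels(self):
        rng = np.random.default_rng(1)
        psms = [
            make_psm(f"p{i}", float(rng.normal(8, 3)), decoy=i % 5 == 0)
            for i in range(500)
        ]
        small = {p.psm_id for p in estimate_fdr_threshold(psms, 0.01).accepted}
        large = {p.psm_id for p in estimate_fdr_threshold(psms, 0.10).accepted}
        assert small <= large

    def test_run_scope_applies_per_run_then_aggregate(self):
        good = [make_psm(f"g{i}", 12.0, run_id="run1") for i in range(50)]
        bad = [make_psm(f"b{i}", 6.0, run_id="run2") for i in range(50)]
        bad_decoys = [make_psm(f"bd{i}", 6.5, decoy=True, run_id="run2")
                      for i in range(20)]
        res = estimate_fdr_threshold(good + bad + bad_decoys, 0.01, scope="run")
        assert "run1" in res.cutoffs and "run2" in res.cutoffs
        accepted_runs = {p.run_id for p in res.accepted}
        assert accepted_runs == {"run1"}  # run2 cannot reach 1% FDR

    def test_no_targets_rejected(self):
        with pytest.raises(ValueError, match="no target"):
            estimate_fdr_threshold([make_psm("d", 5, decoy=True)], 0.01)

    def test_simulation_false_discovery_proportion_controlled(self):
        # small-scale calibration check; the full 50-seed run is in acceptance
        from erv_antigen.synthetic_data import simulate_psm_table

        fdps = []
        for seed in range(5):
            psms, truth = simulate_psm_table(2000, 200, 0.9, seed=seed)
            res = estimate_fdr_threshold(psms, 0.01)
            bad = sum(1 for p in res.accepted if not truth[p.psm_id])
            fdps.append(bad / max(1, len(res.accepted)))
        assert np.mean(fdps) <= 0.02


class TestFixedThresholds:
    def test_inclusive_boundaries_kept(self):
        p = make_psm("p", 7.0, spi_pct=50.0, bcs=5.0, charge=2, peptide="AAAAAAAAA")
        assert apply_fixed_thresholds([p]) == [p]

    @pytest.mark.parametrize(
        "kw",
        [
            {"sm_score": 6.9}, {"spi_pct": 49.9}, {"bcs": 4.9},
            {"charge": 5}, {"charge": 0},
            {"peptide": "AAAAAAAAAAAA"},  # length 12
            {"peptide": "AAAAAAA"},  # length 7
        ],
    )
    def test_violations_removed(self, kw):
        base = dict(peptide="AAAAAAAAA", charge=2, spi_pct=60.0, bcs=6.0)
        base.update({k: v for k, v in kw.items() if k != "sm_score"})
        score = kw.get("sm_score", 9.0)
        p = make_psm("p", score, **base)
        assert apply_fixed_thresholds([p]) == []


class TestSpectralAngle:
    def test_identical_spectra(self):
        v = {"b2": 3.0, "y4": 1.0}
        assert spectral_angle(v, v) == pytest.approx(1.0)

    def test_orthogonal_spectra(self):
        assert spectral_angle({"b2": 1.0}, {"y2": 1.0}) == pytest.approx(0.0)

    def test_closed_form_half(self):
        # a=(1,0), b=(1,1): cos = 1/sqrt(2) -> sa = 1 - 2*(pi/4)/pi = 0.5
        assert spectral_angle({"b2": 1.0}, {"b2": 1.0, "y2": 1.0}) == pytest.approx(0.5)

    def test_both_zero_is_zero(self):
        assert spectral_angle({}, {}) == 0.0
        assert spectral_angle({"b2": 0.0}, {"y2": 0.0}) == 0.0

    def test_negative_intensity_rejected(self):
        with pytest.raises(ValueError):
            spectral_angle({"b2": -1.0}, {"b2": 1.0})

    @settings(max_examples=50, deadline=None)
    @given(
        st.lists(st.floats(0.01, 1e3), min_size=1, max_size=6),
        st.floats(0.1, 100.0),
    )
    def test_property_scale_invariance_and_symmetry(self, vals, scale):
        a = {f"i{k}": v for k, v in enumerate(vals)}
        b = {f"i{k}": v * 2 + 1 for k, v in enumerate(vals)}
        sa = spectral_angle(a, b)
        assert 0.0 <= sa <= 1.0
        assert spectral_angle(b, a) == pytest.approx(sa)
        # arccos is ill-conditioned near cos = 1, so allow modest slack
        scaled = {k: v * scale for k, v in a.items()}
        assert spectral_angle(scaled, b) == pytest.approx(sa, abs=1e-4)


class TestRtCalibration:
    def test_single_segment_top_two(self):
        psms = [make_psm(f"p{i}", s, source_class="reference")
                for i, s in enumerate([9, 8, 7])]
        subset = select_rt_calibration(psms, n_segments=1, top_k=2)
        assert {p.sm_score for p in subset} == {9, 8}

    def test_non_reference_excluded(self):
        psms = [make_psm("p", 9, source_class="erv")]
        assert select_rt_calibration(psms, 1, 2) == []

    def test_empty_input(self):
        assert select_rt_calibration([], 50, 15) == []

    def test_binning_matches_brute_force(self):
        rng = np.random.default_rng(3)
        psms = [
            make_psm(f"p{i}", float(rng.normal(10, 2)),
                     rt_obs_min=float(rng.uniform(0, 100)),
                     source_class="reference")
            for i in range(400)
        ]
        # pin the RT range so bin width is exactly 2.0
        psms += [make_psm("lo", 1, rt_obs_min=0.0),
                 make_psm("hi", 1, rt_obs_min=100.0)]
        subset = {p.psm_id for p in select_rt_calibration(psms, 50, 3)}
        brute: dict[int, list] = {}
        for p in psms:
            if p.source_class != "reference":
                continue
            idx = min(49, int(p.rt_obs_min / 2.0))
            brute.setdefault(idx, []).append(p)
        expect = set()
        for members in brute.values():
            expect |= {
                p.psm_id
                for p in sorted(members, key=lambda x: -x.sm_score)[:3]
            }
        assert subset == expect


class TestStrikes:
    def test_all_pass(self):
        r = strike_classify(0.7, 5.0, 1.0)
        assert (r.strikes, r.verdict) == (0, "pass")

    def test_one_strike_maybe(self):
        r = strike_classify(0.5, 5.0, 1.0)
        assert (r.strikes, r.verdict) == (1, "maybe")

    def test_three_strikes_fail(self):
        r = strike_classify(0.5, 12.0, 2.5)
        assert (r.strikes, r.verdict) == (3, "fail")

    def test_boundary_semantics(self):
        assert strike_classify(0.6, 0, 0).strikes == 1  # pass needs > 0.6
        assert strike_classify(0.61, 10.0, 0).strikes == 0  # within +/- 10 passes
        assert strike_classify(0.61, -10.0, 0).strikes == 0
        assert strike_classify(0.61, 0, 2.0).strikes == 1  # pass needs < 2.0

    def test_exhaustive_eight_combinations(self):
        pass_vals = {"sa": 0.9, "rt": 0.0, "rank": 0.1}
        fail_vals = {"sa": 0.2, "rt": 30.0, "rank": 5.0}
        for bits in itertools.product([0, 1], repeat=3):
            sa = pass_vals["sa"] if bits[0] else fail_vals["sa"]
            rt = pass_vals["rt"] if bits[1] else fail_vals["rt"]
            rank = pass_vals["rank"] if bits[2] else fail_vals["rank"]
            r = strike_classify(sa, rt, rank)
            expected_strikes = 3 - sum(bits)
            assert r.strikes == expected_strikes
            assert r.verdict == {0: "pass", 1: "maybe"}.get(expected_strikes, "fail")


class TestBinderCategory:
    @pytest.mark.parametrize(
        "rank,expected",
        [(0.03, "strong"), (0.499, "strong"), (0.5, "weak"), (2.0, "weak"),
         (2.001, "non"), (2.5, "non")],
    )
    def test_brackets(self, rank, expected):
        assert binder_category(rank) == expected

    def test_negative_rejected(self):
        with pytest.raises(ValueError):
            binder_category(-0.1)

    def test_boundary_inconsistency_documented(self):
        # rank 2.0 is a weak binder by category but still a binding strike
        assert binder_category(2.0) == "weak"
        assert strike_classify(0.9, 0.0, 2.0).strikes == 1


class TestSequenceTag:
    def test_two_residue_tag(self):
        peaks = [200.0, 257.02146, 328.05857]  # +Gly, +Ala
        assert sequence_tag_length(peaks, tol=0.01) == 2

    def test_single_gap_fails_quality(self):
        assert sequence_tag_length([200.0, 257.02146], tol=0.01) == 1

    def test_no_matched_gaps(self):
        assert sequence_tag_length([100.0, 120.0, 140.0], tol=0.01) == 0

    def test_empty_and_tolerance_validation(self):
        assert sequence_tag_length([]) == 0
        with pytest.raises(ValueError):
            sequence_tag_length([1.0], tol=0)

    def test_longest_path_not_greedy(self):
        g = 57.02146
        peaks = [100.0, 100.0 + g, 100.0 + 2 * g, 100.0 + 3 * g, 500.0]
        assert sequence_tag_length(peaks, tol=0.001) == 3


class TestMasses:
    def test_gg_mass(self):
        assert peptide_monoisotopic_mass("GG") == pytest.approx(132.05349, abs=1e-4)

    def test_lys8_shift_rounds_to_eight(self):
        shift = label_shift("lys8")
        assert shift == pytest.approx(8.0142, abs=1e-3)
        assert round(shift) == 8

    def test_modifications_applied_per_residue(self):
        plain = peptide_monoisotopic_mass("ACK")
        cam = peptide_monoisotopic_mass("ACK", {"C": 57.02146})
        assert cam - plain == pytest.approx(57.02146)

    def test_empty_and_unknown_rejected(self):
        with pytest.raises(ValueError):
            peptide_monoisotopic_mass("")
        with pytest.raises(ValueError):
            peptide_monoisotopic_mass("AB")
        with pytest.raises(ValueError):
            label_shift("arg10")

    def test_heavy_peptide_mass_is_light_plus_shift(self):
        light = peptide_monoisotopic_mass("ATFLGSLTGK")
        heavy = peptide_monoisotopic_mass("ATFLGSLTGK", {"K": label_shift()})
        assert heavy - light == pytest.approx(label_shift())


class TestHamming:
    def test_printed_peptides_differ_by_one(self):
        assert hamming_distance("ATFLGSLTGK", "ATFLGSLTWK") == 1

    def test_length_mismatch(self):
        with pytest.raises(ValueError):
            hamming_distance("AA", "AAA")


class TestFinalize:
    @pytest.fixture
    def erv_db(self):
        reference = [("REF1", "MKTAYIAKQRQISFVKSHFSRQ")]
        orfs = [
            OrfProtein("ERV0001", 1, 0, "GGLLDPKTGSWWTGGVVNNPPQQRRSSTT"),
            OrfProtein("ERV0002", 2, 0, "HHWWNNDDEEFFGGMMPPQQVVYY"),
        ]
        return build_search_db(reference, orfs)

    def _psm(self, psm_id, peptide, score=10.0, tissue="tumor", **kw):
        return make_psm(psm_id, score, peptide=peptide, tissue=tissue, **kw)

    def _strike(self, psm_id, verdict):
        sa = {"pass": 0.9, "maybe": 0.5, "fail": 0.2}[verdict]
        rt = 30.0 if verdict != "fail" else 0.0
        # fail needs two strikes
        return strike_classify(sa, 0.0 if verdict != "fail" else 20.0, 0.1, psm_id)

    def test_normal_tissue_exclusion(self, erv_db):
        pep = "LLDPKTGSW"
        psms = [
            self._psm("a", pep),
            self._psm("b", pep, tissue="normal", sample_id="n1"),
        ]
        maps = {pep: map_peptide_sources(pep, erv_db)}
        strikes = {"a": self._strike("a", "pass")}
        out = finalize_peptide_calls(psms, maps, strikes)
        assert out.audit["normal_tissue"] == 0 and out.calls == []

    def test_cysteine_removed(self, erv_db):
        pep = "ACDEFGHIK"
        psms = [self._psm("a", pep)]
        maps = {pep: map_peptide_sources(pep, erv_db)}
        # force it past stage 1 by faking an ERV-exclusive map
        class FakeMap:
            erv_exclusive = True
            source_ervs = ("ERV0001",)
        out = finalize_peptide_calls(psms, {pep: FakeMap()},
                                     {"a": self._strike("a", "pass")})
        assert out.audit["cysteine"] == 0

    def test_reference_collision_removed(self, erv_db):
        pep = "MKTAYIAKQ"  # verbatim in REF1
        out = finalize_peptide_calls(
            [self._psm("a", pep)], {pep: map_peptide_sources(pep, erv_db)},
            {"a": self._strike("a", "pass")},
        )
        assert out.audit["reference_collision"] == 0

    def test_il_aware_normal_exclusion(self, erv_db):
        pep = "LLDPKTGSW"
        out = finalize_peptide_calls(
            [self._psm("a", pep)],
            {pep: map_peptide_sources(pep, erv_db)},
            {"a": self._strike("a", "pass")},
            normal_peptides=["ILDPKTGSW"],  # I/L variant of pep
        )
        assert out.audit["normal_tissue"] == 0

    def test_ten_peptide_fixture_audit(self, erv_db):
        # hand-enumerated outcomes for a constructed 10-PSM fixture
        peps = {
            "keep1": "LLDPKTGSW",     # survives everything
            "keep2": "WWNNDDEEF",     # survives everything
            "ref": "MKTAYIAKQ",       # stage 1: reference collision
            "norm": "GGLLDPKTG",      # stage 2: seen in normal tissue
            "dup": "DPKTGSWWT",       # stage 3: duplicate of itself
            "cys": "GGMMPPQQC",       # stage 4: cysteine (fake map below)
            "fail": "NNPPQQRRS",      # stage 5: two strikes
        }
        psms = [
            self._psm("p1", peps["keep1"]),
            self._psm("p2", peps["keep2"]),
            self._psm("p3", peps["ref"]),
            self._psm("p4", peps["norm"]),
            self._psm("p5", peps["dup"], score=11.0),
            self._psm("p6", peps["dup"], score=9.0),
            self._psm("p7", peps["cys"]),
            self._psm("p8", peps["fail"]),
            self._psm("p9", peps["norm"], tissue="normal", sample_id="n1"),
        ]
        class FakeMap:
            erv_exclusive = True
            source_ervs = ("ERV0001",)
        maps = {p: map_peptide_sources(p, erv_db) for p in peps.values()}
        maps[peps["cys"]] = FakeMap()
        strikes = {
            "p1": self._strike("p1", "pass"),
            "p2": self._strike("p2", "maybe"),
            "p5": self._strike("p5", "pass"),
            "p6": self._strike("p6", "pass"),
            "p7": self._strike("p7", "pass"),
            "p8": strike_classify(0.2, 20.0, 0.1, "p8"),  # 2 strikes -> fail
        }
        out = finalize_peptide_calls(psms, maps, strikes)
        assert out.audit == {
            "input": 8,                 # p9 is normal tissue, not a call
            "reference_collision": 7,   # - p3
            "normal_tissue": 6,         # - p4
            "redundancy": 5,            # p5/p6 collapse
            "cysteine": 4,              # - p7
            "strike_fail": 3,           # - p8
        }
        counts = list(out.audit.values())
        assert counts == sorted(counts, reverse=True)
        kept = {c.peptide for c in out.calls}
        assert kept == {peps["keep1"], peps["keep2"], peps["dup"]}
        dup_call = next(c for c in out.calls if c.peptide == peps["dup"])
        assert dup_call.psm_id == "p5"  # best-scoring PSM representative

    def test_missing_strike_names_psm(self, erv_db):
        pep = "LLDPKTGSW"
        with pytest.raises(KeyError, match="a"):
            finalize_peptide_calls(
                [self._psm("a", pep)], {pep: map_peptide_sources(pep, erv_db)}, {}
            )

    def test_missing_source_map_names_peptide(self, erv_db):
        with pytest.raises(KeyError, match="LLDPKTGSW"):
            finalize_peptide_calls([self._psm("a", "LLDPKTGSW")], {}, {})


class TestPsmTsv:
    def test_round_trip(self, tmp_path):
        psms = [
            make_psm("p1", 9.5, by_obs={"b2": 1.5, "y3": 2.0},
                     by_pred={"b2": 1.4, "y3": 2.2}),
            make_psm("p2", 4.0, decoy=True),
        ]
        path = tmp_path / "psms.tsv"
        write_psm_tsv(psms, path)
        back = read_psm_tsv(path)
        assert [p.psm_id for p in back] == ["p1", "p2"]
        assert back[0].by_obs == {"b2": 1.5, "y3": 2.0}
        assert back[1].is_decoy

    def test_bad_header(self, tmp_path):
        path = tmp_path / "psms.tsv"
        path.write_text("a\tb\n")
        with pytest.raises(ValueError, match="header"):
            read_psm_tsv(path)
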