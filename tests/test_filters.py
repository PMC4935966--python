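"""Variant filter rules: read support, strand balance, genotype windows,
damaging consensus, rarity and the cross-cohort artifact screen."""
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from helpers import make_variant
from syclone import filters as flt
from syclone.model import Effect, PredictorCall, ValidationError

D, B, M = PredictorCall.DAMAGING, PredictorCall.BENIGN, PredictorCall.MISSING


class TestTumourFilters:
    @pytest.mark.parametrize(
        "alt,total,fplus,expected_fail",
        [
            (10, 200, 0.5, None),  # every threshold met at its boundary
            (9, 20, 0.5, "min_alt_reads"),
            (50, 100, 0.995, "strand_balance"),
            (10, 250, 0.5, "min_vaf"),  # f = 4% < 5%
        ],
    )
    def test_threshold_boundaries(self, alt, total, fplus, expected_fail):
        v = make_variant(
            alt_reads=alt, total_reads=total, frac_plus=fplus, frac_minus=1 - fplus
        )
        decision = flt.pass_tumour_filters(v)
        if expected_fail is None:
            assert decision.passed
        else:
            assert not decision.passed
            assert expected_fail in decision.failed_rules

    def test_zero_coverage_is_an_error(self):
        v = make_variant(alt_reads=0, total_reads=0)
        with pytest.raises(ValidationError):
            flt.pass_tumour_filters(v)


class TestNormalFilters:
    @pytest.mark.parametrize(
        "alt,fplus,passed",
        [(2, 0.9, True), (1, 0.5, False), (5, 1.0, False)],
    )
    def test_two_read_and_strand_rules(self, alt, fplus, passed):
        v = make_variant(
            alt_reads=alt, total_reads=100, frac_plus=fplus, frac_minus=1 - fplus
        )
        assert flt.pass_normal_filters(v).passed is passed


class TestRoundMergingAndSubtraction:
    def _set(self, positions):
        return [make_variant(pos=p) for p in positions]

    def test_tumour_rounds_are_intersected(self):
        merged = flt.merge_sequencing_rounds(
            self._set([1, 2]), self._set([2, 3]), mode="tumour"
        )
        assert [v.pos for v in merged] == [2]

    def test_normal_rounds_are_unioned(self):
        merged = flt.merge_sequencing_rounds(
            self._set([1, 2]), self._set([2, 3]), mode="normal"
        )
        assert sorted(v.pos for v in merged) == [1, 2, 3]

    def test_identical_rounds_unchanged(self):
        r = self._set([1, 2, 3])
        assert flt.merge_sequencing_rounds(r, r, mode="tumour") == r
        assert flt.merge_sequencing_rounds(r, r, mode="normal") == r

    def test_counts_come_from_round_one(self):
        r1 = [make_variant(pos=5, alt_reads=20, total_reads=80)]
        r2 = [make_variant(pos=5, alt_reads=11, total_reads=40)]
        (merged,) = flt.merge_sequencing_rounds(r1, r2, mode="tumour")
        assert merged.alt_reads == 20 and merged.total_reads == 80

    @given(
        t=st.sets(st.integers(1, 30)),
        n=st.sets(st.integers(1, 30)),
    )
    @settings(max_examples=50, deadline=None)
    def test_subtraction_partitions_the_tumour_set(self, t, n):
        tumour = self._set(sorted(t))
        normal = self._set(sorted(n))
        somatic = {v.pos for v in flt.subtract_germline(tumour, normal)}
        shared = t & n
        assert somatic | shared == t
        assert somatic & shared == set()


class TestGermlineSNPFilter:
    @pytest.mark.parametrize(
        "alt,total,passed",
        [
            (45, 100, True),  # heterozygous window
            (70, 100, False),  # between the windows
            (95, 100, True),  # homozygous window
            (40, 100, True),  # inclusive lower edge
            (60, 100, True),  # inclusive upper edge
            (90, 100, False),  # homozygous bound is strict
            (9, 20, False),  # VAF 45% but under 10 supporting reads
        ],
    )
    def test_genotype_vaf_windows(self, alt, total, passed):
        v = make_variant(alt_reads=alt, total_reads=total)
        assert flt.pass_germline_snp_filters(v).passed is passed


class TestDamagingAndRarity:
    @pytest.mark.parametrize(
        "effect,calls,expected",
        [
            (Effect.STOPGAIN, (B,) * 5, True),
            (Effect.STOPLOSS, (M,) * 5, True),
            (Effect.NONSYNONYMOUS, (D, D, D, D, B), True),
            (Effect.NONSYNONYMOUS, (D, D, D, B, B), False),
            (Effect.NONSYNONYMOUS, (D, D, D, D, M), True),
            (Effect.NONSYNONYMOUS, (D, D, D, M, M), False),  # missing = benign vote
            (Effect.SYNONYMOUS, (D,) * 5, False),
            (Effect.FRAMESHIFT, (D,) * 5, False),  # consensus applies to missense only
        ],
    )
    def test_consensus_rule(self, effect, calls, expected):
        v = make_variant(effect=effect, predictor_calls=calls)
        assert flt.is_damaging(v) is expected

    def test_missing_calls_can_abstain_with_flag(self):
        cfg = flt.FilterConfig(missing_predictor_abstains=True)
        v = make_variant(predictor_calls=(D, D, D, M, M))  # 3/3 available
        assert flt.is_damaging(v, cfg) is True

    @pytest.mark.parametrize(
        "mafs,expected",
        [
            ((None, None), True),
            ((0.005, 0.009), True),
            ((0.02, None), False),
            ((0.01, None), False),  # threshold is strict
        ],
    )
    def test_rarity_rule(self, mafs, expected):
        assert flt.is_rare(make_variant(maf_panels=mafs)) is expected


class TestCohortArtifactFilter:
    KEY = ("chr1", 100, "A", "T")

    def _cohorts(self, n_carriers, n_total):
        samples = {f"s{i}": [self.KEY] if i < n_carriers else [] for i in range(n_total)}
        return {"cohort1": samples}

    def test_widely_shared_unknown_variant_removed(self):
        retained = flt.cohort_artifact_filter(self._cohorts(60, 100), {self.KEY: False})
        assert self.KEY not in retained

    def test_exactly_half_is_retained(self):
        retained = flt.cohort_artifact_filter(self._cohorts(50, 100), {self.KEY: False})
        assert self.KEY in retained

    def test_panel_presence_exempts(self):
        retained = flt.cohort_artifact_filter(self._cohorts(90, 100), {self.KEY: True})
        assert self.KEY in retained

    def test_empty_cohort_is_an_error(self):
        with pytest.raises(ValueError):
            flt.cohort_artifact_filter({"c": {}}, {})

    def test_per_cohort_mode_requires_every_cohort(self):
        cohorts = {
            "a": {f"s{i}": [self.KEY] for i in range(10)},  # 100% carriers
            "b": {f"s{i}": [self.KEY] if i < 2 else [] for i in range(10)},  # 20%
        }
        pooled = flt.cohort_artifact_filter(cohorts, {self.KEY: False})
        assert self.KEY not in pooled  # 12/20 pooled > 50%
        per = flt.cohort_artifact_filter(
            cohorts, {self.KEY: False}, flt.FilterConfig(cohort_artifact_per_cohort=True)
        )
        assert self.KEY in per  # cohort b is below 50%


class TestRareDamagingChain:
    def test_recovers_exactly_the_planted_set(self):
        planted = [
            make_variant(pos=p, alt_reads=50, total_reads=100,
                         effect=Effect.STOPGAIN, maf_panels=(None, None))
            for p in (10, 20, 30)
        ]
        decoys = [
            # common variant
            make_variant(pos=40, alt_reads=50, total_reads=100,
                         effect=Effect.STOPGAIN, maf_panels=(0.1, None)),
            # benign missense
            make_variant(pos=50, alt_reads=50, total_reads=100,
                         predictor_calls=(D, B, B, B, B)),
            # somatic-like VAF, outside the genotype windows
            make_variant(pos=60, alt_reads=20, total_reads=100,
                         effect=Effect.STOPGAIN),
            # weak read support
            make_variant(pos=70, alt_reads=5, total_reads=10,
                         effect=Effect.STOPGAIN),
        ]
        kept = flt.rare_damaging_chain(planted + decoys)
        assert kept == planted

    def test_rule_order_does_not_matter(self):
        variants = [
            make_variant(pos=p, alt_reads=a, total_reads=100,
                         effect=e, predictor_calls=c, maf_panels=m)
            for p, a, e, c, m in [
                (1, 45, Effect.STOPGAIN, (M,) * 5, (None, None)),
                (2, 45, Effect.NONSYNONYMOUS, (D, D, D, D, B), (0.002, None)),
                (3, 30, Effect.STOPGAIN, (M,) * 5, (None, None)),
                (4, 45, Effect.NONSYNONYMOUS, (D, D, B, B, B), (None, None)),
                (5, 45, Effect.STOPGAIN, (M,) * 5, (0.5, None)),
            ]
        ]
        chain_order = {v.key for v in flt.rare_damaging_chain(variants)}
        reordered = {
            v.key
            for v in variants
            if flt.is_rare(v)
            and flt.is_damaging(v)
            and flt.pass_germline_snp_filters(v).passed
        }
        assert chain_order == reordered
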