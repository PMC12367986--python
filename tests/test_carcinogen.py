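"""Carcinogen decision tree: MoA, POD selection, HBGV/MOE/TTC routing."""

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ltlrisk.carcinogen import (
    CarcRoute,
    MoA,
    NoPODError,
    TTCVerdict,
    assess_carcinogen,
    classify_moa,
    derive_hbgv,
    margin_of_exposure,
    select_pod,
    ttc_screen,
)
from ltlrisk.dossier import (
    CarcinogenClass,
    ChemicalDossier,
    CramerClass,
    DurationClass,
    InVivoScope,
    MoAEvidence,
    PODRecord,
    PodType,
    TriState,
    TTC_REGISTRY,
    UncertaintyFactorSet,
)
from ltlrisk.exposure import DoseMetrics, DoseMode


def metrics(add=1.5e-4, bw=70.0):
    return DoseMetrics(add=add, ladd=add / 100, adr=add, metric_used=DoseMode.ADD,
                       bw_kg=bw)


class TestClassifyMoA:
    def test_positive_genotoxicity_lines_are_linear(self):
        ev = MoAEvidence(structural_alert=TriState.positive, ames=TriState.positive)
        assert classify_moa(ev) is MoA.linear

    def test_multi_species_multi_organ_is_linear(self):
        ev = MoAEvidence(in_vivo_scope=InVivoScope.multi_species_multi_organ)
        assert classify_moa(ev) is MoA.linear

    def test_negative_lines_with_narrow_in_vivo_are_nonlinear(self):
        ev = MoAEvidence(structural_alert=TriState.negative, ames=TriState.negative,
                         in_vivo_scope=InVivoScope.single_species_single_organ)
        assert classify_moa(ev) is MoA.nonlinear

    def test_all_unknown_defaults_to_linear(self):
        assert classify_moa(MoAEvidence()) is MoA.unknown_default_linear

    def test_any_positive_trumps_negatives(self):
        # Precautionary arbitration: a positive Ames overrides a negative alert.
        ev = MoAEvidence(structural_alert=TriState.negative, ames=TriState.positive,
                         in_vivo_scope=InVivoScope.single_species_single_organ)
        assert classify_moa(ev) is MoA.linear


class TestSelectPOD:
    def test_bmdl10_preferred_even_when_higher(self):
        pods = [PODRecord(pod_type=PodType.NOAEL, value=5.0),
                PODRecord(pod_type=PodType.BMDL10, value=8.0)]
        assert select_pod(pods).value == 8.0

    def test_single_loael_is_accepted(self):
        pod = select_pod([PODRecord(pod_type=PodType.LOAEL, value=2.0)])
        assert pod.pod_type is PodType.LOAEL and pod.value == 2.0

    def test_tie_broken_by_lowest_value(self):
        # Exhaustive-comparison oracle over the candidate list.
        pods = [PODRecord(pod_type=PodType.NOAEL, value=5.0),
                PODRecord(pod_type=PodType.NOAEL, value=3.0)]
        best = select_pod(pods)
        assert best.value == min(p.value for p in pods) == 3.0

    def test_empty_list_routes_toward_moe_ttc(self):
        with pytest.raises(NoPODError):
            select_pod([])


class TestDeriveHBGV:
    def test_default_100_composition(self):
        pod = PODRecord(pod_type=PodType.NOAEL, value=10.0)
        assert derive_hbgv(pod, UncertaintyFactorSet.default_100()) == pytest.approx(0.1)

    def test_subdivided_product(self):
        # Independent product: 2.5 x 3.16 x 3.16 x 4 = 99.856
        pod = PODRecord(pod_type=PodType.BMDL10, value=5.0)
        uf = UncertaintyFactorSet(interspecies_td=2.5, intraspecies_tk=3.16,
                                  intraspecies_td=3.16, interspecies_tk=4.0)
        assert derive_hbgv(pod, uf) == pytest.approx(5.0 / 99.856)

    def test_loael_requires_extra_factor(self):
        pod = PODRecord(pod_type=PodType.LOAEL, value=10.0)
        with pytest.raises(ValueError):
            derive_hbgv(pod, UncertaintyFactorSet.default_100())
        uf = UncertaintyFactorSet(interspecies_tk=10, intraspecies_tk=10,
                                  loael_to_noael=3.0)
        assert derive_hbgv(pod, uf) == pytest.approx(10.0 / 300.0)

    @settings(derandomize=True, max_examples=50)
    @given(st.floats(min_value=1.0, max_value=50.0))
    def test_monotone_decreasing_in_every_component(self, bump):
        pod = PODRecord(pod_type=PodType.NOAEL, value=10.0)
        base_uf = UncertaintyFactorSet(interspecies_tk=10, intraspecies_tk=10)
        base = derive_hbgv(pod, base_uf)
        for name in base_uf.components():
            bumped = base_uf.model_copy(
                update={name: getattr(base_uf, name) * (1 + bump)})
            assert derive_hbgv(pod, bumped) < base


class TestMarginOfExposure:
    def test_simple_ratio(self):
        pod = PODRecord(pod_type=PodType.BMDL10, value=1.0)
        assert margin_of_exposure(pod, 1e-4) == pytest.approx(10_000)

    def test_pod_equal_exposure_gives_one(self):
        pod = PODRecord(pod_type=PodType.BMDL10, value=0.5)
        assert margin_of_exposure(pod, 0.5) == pytest.approx(1.0)

    def test_case_study_scale_dose(self):
        pod = PODRecord(pod_type=PodType.BMDL10, value=0.5)
        assert margin_of_exposure(pod, 1.5e-4) == pytest.approx(3333.3, rel=1e-4)

    def test_zero_exposure_is_not_divided(self):
        pod = PODRecord(pod_type=PodType.BMDL10, value=0.5)
        with pytest.raises(ZeroDivisionError, match="no exposure"):
            margin_of_exposure(pod, 0.0)


class TestTTCScreen:
    def make(self, cls):
        return ChemicalDossier(name="probe", cramer_class=cls)

    def test_genotoxic_low_intake_below(self):
        verdict, thr = ttc_screen(self.make(CramerClass.genotoxic),
                                  intake_ug_per_day=0.1)
        assert verdict is TTCVerdict.below_ttc and thr == 0.15

    def test_boundary_intake_is_compliant(self):
        verdict, _ = ttc_screen(self.make(CramerClass.III), intake_ug_per_day=90.0)
        assert verdict is TTCVerdict.below_ttc

    def test_water_mode_exceedance(self):
        verdict, thr = ttc_screen(self.make(CramerClass.I), water_conc_ug_per_L=40.0)
        assert verdict is TTCVerdict.exceeds_ttc and thr == 37.7

    def test_water_mode_unsupported_for_classes_without_target(self):
        for cls in (CramerClass.II, CramerClass.organophosphate_carbamate):
            with pytest.raises(ValueError):
                ttc_screen(self.make(cls), water_conc_ug_per_L=1.0)

    def test_verdicts_match_brute_force_for_all_classes(self):
        # 6 classes x {below, at, above} probes against the raw registry.
        for cls, entry in TTC_REGISTRY.items():
            for factor in (0.5, 1.0, 2.0):
                intake = entry.ttc_ug_per_day * factor
                verdict, _ = ttc_screen(self.make(cls), intake_ug_per_day=intake)
                expected = (TTCVerdict.exceeds_ttc if intake > entry.ttc_ug_per_day
                            else TTCVerdict.below_ttc)
                assert verdict is expected

    def test_requires_exactly_one_mode(self):
        with pytest.raises(ValueError):
            ttc_screen(self.make(CramerClass.I))
        with pytest.raises(ValueError):
            ttc_screen(self.make(CramerClass.I), intake_ug_per_day=1,
                       water_conc_ug_per_L=1)


class TestAssessCarcinogen:
    def test_lead_routes_to_hbgv(self, pb_dossier):
        a = assess_carcinogen(pb_dossier, metrics(), DurationClass.short)
        assert a.route is CarcRoute.hbgv
        assert a.moa is MoA.nonlinear
        assert a.hbgv == pytest.approx(1.4e-3)
        assert not a.alara

    def test_genotoxic_no_pod_routes_to_ttc_with_alara(self):
        d = ChemicalDossier(name="g",
                            carcinogen_class=CarcinogenClass.non_threshold_carcinogen,
                            assume_genotoxic_default=True,
                            cramer_class=CramerClass.genotoxic)
        # intake 0.05 µg/day: add = 0.05 / (70 x 1000)
        a = assess_carcinogen(d, metrics(add=0.05 / 70e3), DurationClass.short)
        assert a.route is CarcRoute.ttc
        assert a.ttc_verdict is TTCVerdict.below_ttc
        assert a.alara
        # Stepwise branch check: MoA resolved, ALARA noted, TTC compared.
        ids = [b.branch_id for b in a.trace]
        assert ids[0].startswith("moa.")
        assert "alara" in ids
        assert "ttc.compare" in ids

    def test_linear_with_pod_routes_to_moe(self):
        d = ChemicalDossier(name="m",
                            carcinogen_class=CarcinogenClass.non_threshold_carcinogen,
                            assume_genotoxic_default=True,
                            pods=[PODRecord(pod_type=PodType.BMDL10, value=0.5)])
        a = assess_carcinogen(d, metrics(), DurationClass.short)
        assert a.route is CarcRoute.moe
        assert a.moe == pytest.approx(0.5 / 1.5e-4)

    def test_no_data_is_inconclusive_not_an_exception(self):
        d = ChemicalDossier(name="n", carcinogen_class=CarcinogenClass.unknown)
        a = assess_carcinogen(d, metrics(), DurationClass.short)
        assert a.route in (CarcRoute.alara, CarcRoute.inconclusive)

    def test_non_carcinogen_is_a_precondition_error(self):
        d = ChemicalDossier(name="x",
                            carcinogen_class=CarcinogenClass.non_carcinogen)
        with pytest.raises(ValueError):
            assess_carcinogen(d, metrics(), DurationClass.short)

    def test_deterministic_and_replayable(self, pb_dossier):
        a1 = assess_carcinogen(pb_dossier, metrics(), DurationClass.short)
        a2 = assess_carcinogen(pb_dossier, metrics(), DurationClass.short)
        assert a1.to_dict() == a2.to_dict()
        assert a1.trace.replay()
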