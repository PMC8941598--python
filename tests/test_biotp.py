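"""bioTP mass prediction, ppm matching, control filtering, CL assignment."""

import numpy as np
import pandas as pd
import pytest

from zftox import chem
from zftox.biotp import (
    AnnotationConfig,
    EvidenceRecord,
    annotate_biotps,
    assign_confidence_level,
    dedupe_adducts,
    flag_insource_ambiguity,
    match_features_ppm,
    negative_control_filter,
    predict_biotp_masses,
)
from zftox.synthetic import reference_spectrum_library, simulate_query_spectra
from conftest import build_table


def test_epoxidation_mass_against_oracle():
    cands = predict_biotp_masses("C15H12N2O")
    ep = next(c for c in cands if c.rule == "epoxidation")
    assert ep.formula == "C15H12N2O2"
    # oracle: atomic-mass sum C15 H12 N2 O2 plus a proton
    oracle = (15 * 12.0 + 12 * 1.00782503207 + 2 * 14.0030740048
              + 2 * 15.9949146196)
    assert abs(ep.neutral_mass - oracle) < 1e-4
    assert abs(ep.expected_mz["[M+H]"] - (oracle + 1.007276)) < 1e-4


def test_identity_rule_gives_parent_adduct_mass():
    cands = predict_biotp_masses("C15H12N2O")
    parent = next(c for c in cands if c.rule == "parent")
    m = chem.monoisotopic_mass("C15H12N2O")
    assert parent.expected_mz["[M+H]"] == pytest.approx(m + 1.007276, abs=1e-6)


def test_impossible_rule_skipped_with_warning():
    rules = [chem.TransformationRule("desulfuration", remove="S")]
    with pytest.warns(UserWarning, match="desulfuration"):
        cands = predict_biotp_masses("C15H12N2O", rules=rules)
    assert cands == []


def _feature_frame(mzs: dict[str, float]) -> pd.DataFrame:
    return pd.DataFrame(
        {"mz": list(mzs.values()), "rt_seconds": 100.0, "assay": "nontarget"},
        index=pd.Index(list(mzs), name="feature_id"),
    )


def test_ppm_matching_boundaries():
    cands = predict_biotp_masses("C15H12N2O")
    ep_mz = next(c for c in cands if c.rule == "epoxidation").expected_mz["[M+H]"]
    feats = _feature_frame({
        "exact": ep_mz,
        "six_ppm": ep_mz * (1 + 6e-6),
        "three_ppm": ep_mz * (1 - 3e-6),
    })
    matched = {m.feature_id for m in match_features_ppm(feats, cands, tol_ppm=5.0)}
    assert matched == {"exact", "three_ppm"}
    exact = next(m for m in match_features_ppm(feats, cands) if m.feature_id == "exact")
    assert exact.ppm_error == pytest.approx(0.0, abs=1e-9)


def test_matching_is_tolerance_monotone():
    cands = predict_biotp_masses("C15H12N2O")
    rng = np.random.default_rng(0)
    mzs = {f"f{i}": float(rng.uniform(150, 450)) for i in range(50)}
    for i, c in enumerate(cands[:5]):
        mzs[f"near{i}"] = c.expected_mz["[M+H]"] * (1 + rng.uniform(-4, 4) * 1e-6)
    feats = _feature_frame(mzs)
    at3 = {(m.feature_id, m.candidate.rule, m.adduct)
           for m in match_features_ppm(feats, cands, 3.0)}
    at5 = {(m.feature_id, m.candidate.rule, m.adduct)
           for m in match_features_ppm(feats, cands, 5.0)}
    assert at3 <= at5


def test_negative_control_filter_any_signal_removes():
    t = build_table(
        {"dosed_only": [0.0, 0.0, 5.0], "in_one_control": [0.0, 3.0, 5.0]},
        ["negative_control", "negative_control", "dose"],
    )
    cands = predict_biotp_masses("C15H12N2O")
    from zftox.biotp import FeatureMatch

    matches = [
        FeatureMatch("dosed_only", cands[0], "[M+H]", 100.0, 0.0),
        FeatureMatch("in_one_control", cands[0], "[M+H]", 100.0, 0.0),
    ]
    kept = negative_control_filter(matches, t)
    assert [m.feature_id for m in kept] == ["dosed_only"]
    assert negative_control_filter([], t) == []


def test_confidence_level_assignment_rules():
    assert assign_confidence_level(EvidenceRecord(standard_similarity=0.95)) == 1
    assert assign_confidence_level(EvidenceRecord(library_score=0.92)) == 2
    assert assign_confidence_level(EvidenceRecord(structure_predicted=True)) == 3
    assert assign_confidence_level(EvidenceRecord(formula_consistent=True)) == 4
    assert assign_confidence_level(EvidenceRecord(has_ms2=False,
                                                  standard_similarity=0.99)) == 5
    assert assign_confidence_level(EvidenceRecord()) == 5
    # boundary: exactly 0.9 is not "above 0.9"
    assert assign_confidence_level(EvidenceRecord(standard_similarity=0.9)) == 2 or \
        assign_confidence_level(EvidenceRecord(standard_similarity=0.9)) == 5


def test_dedupe_fifteen_features_two_adduct_pairs_gives_thirteen():
    triples = [(f"f{i}", f"compound_{i}", "[M+H]") for i in range(11)]
    triples += [("f11", "cytidine", "[M+H]"), ("f12", "cytidine", "[M+K]"),
                ("f13", "histidine", "[M+H]"), ("f14", "histidine", "[M+Na]")]
    assert len(triples) == 15
    assert len(dedupe_adducts(triples)) == 13


def test_dedupe_no_duplicates_identity_and_triple_collapse():
    triples = [("a", "x", "[M+H]"), ("b", "y", "[M+H]")]
    assert dedupe_adducts(triples) == ["x", "y"]
    one = [("a", "x", "[M+H]"), ("b", "x", "[M+Na]"), ("c", "x", "[M+K]")]
    assert dedupe_adducts(one) == ["x"]


def test_dedupe_conflicting_assignment_raises():
    with pytest.raises(ValueError, match="f1"):
        dedupe_adducts([("f1", "x", "[M+H]"), ("f1", "y", "[M+Na]")])


def test_insource_ambiguity_flagging():
    parent = [0.0, 10.0, 50.0, 200.0]
    t = build_table(
        {
            "parent": parent,
            "coeluting": [0.0, 5.0, 25.0, 100.0],
            "far": [0.0, 5.0, 25.0, 100.0],
            "uncorrelated": [90.0, 110.0, 100.0, 95.0],
        },
        ["dose"] * 4,
        rt={"parent": 400.0, "coeluting": 402.0, "far": 520.0, "uncorrelated": 401.0},
    )
    from zftox.biotp import FeatureMatch

    cands = predict_biotp_masses("C15H12N2O")
    for fid, expect in (("coeluting", True), ("far", False), ("uncorrelated", False)):
        m = FeatureMatch(fid, cands[1], "[M+H]", 100.0, 0.0)
        m = flag_insource_ambiguity(m, "parent", t, rt_tol=5.0, min_corr=0.8)
        assert m.insource_ambiguous is expect


def test_annotation_workflow_on_simulated_study(small_study):
    table, truth, cfg = small_study
    spectra = simulate_query_spectra(truth, table, seed=cfg.seed)
    library = reference_spectrum_library(seed=cfg.seed)
    report = annotate_biotps(table, spectra, library, AnnotationConfig())
    # every simulated bioTP feature is matched, nothing else
    assert len(report) == cfg.n_biotp
    assert set(report["feature_id"]) == set(truth.ids_with_label("biotp"))
    # the epoxide and the carbamoyl-loss product are confirmed at CL 1
    cl1 = report[report["confidence_level"] == 1]
    assert sorted(cl1["rule"]) == ["carbamoyl_loss", "epoxidation"]
    # the carbamoyl-loss product co-elutes with the parent: ambiguity flagged
    imi = report[(report["rule"] == "carbamoyl_loss") & (report["adduct"] == "[M+H]")]
    assert bool(imi["insource_ambiguous"].iloc[0])
    # features without MS2 stay at CL 5
    assert (report.loc[~report["has_ms2"], "confidence_level"] == 5).all()
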