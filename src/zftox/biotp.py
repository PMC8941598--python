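"""Biotransformation-product (bioTP) elucidation.

Candidate bioTP masses are predicted by applying elemental transformation rules
to the exposure compound and forming positive-mode adducts; features are matched
at ppm tolerance, filtered on negative-control presence, scored against a local
reference-spectrum library, deduplicated across adducts, and assigned an
identification confidence level on the 1-5 scale used for high-resolution MS
annotation (1 = confirmed against an authentic standard).

External in-silico fragmentation and online spectral-library services are
represented by a pluggable :class:`EvidenceRecord`; a local MGF library of
reference spectra stands in for both.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import chem
from .chem import AdductRule, TransformationRule
from .containers import FeatureTable
from .spectra import MS2Spectrum, ms2_similarity


@dataclass
class BioTPCandidate:
    """A predicted transformation product and its expected adduct masses."""

    rule: str
    formula: str
    neutral_mass: float
    expected_mz: dict  # adduct name -> m/z


@dataclass
class FeatureMatch:
    feature_id: str
    candidate: BioTPCandidate
    adduct: str
    observed_mz: float
    ppm_error: float
    in_negative_control: bool | None = None
    best_similarity: float | None = None
    best_reference: str | None = None
    confidence_level: int = 5
    insource_ambiguous: bool = False


@dataclass
class EvidenceRecord:
    """Identification evidence for one feature.

    standard_similarity: score against an authentic-standard MS2 spectrum;
    library_score: best online/offline spectral-library score (0-1);
    structure_predicted: an in-silico structure prediction consistent with the
    candidate exists; formula_consistent: predicted chemical formulae agree
    across the feature's MS2 spectra.
    """

    standard_similarity: float | None = None
    library_score: float | None = None
    structure_predicted: bool = False
    formula_consistent: bool = False
    has_ms2: bool = True


def predict_biotp_masses(
    parent_formula: str,
    rules: list[TransformationRule] | None = None,
    adducts: list[AdductRule] | None = None,
) -> list[BioTPCandidate]:
    """Candidate per transformation rule with expected m/z for every adduct.

    Rules that would remove atoms the parent lacks are skipped with a warning.
    """
    import warnings

    rules = list(rules) if rules is not None else list(chem.DEFAULT_RULES)
    adducts = list(adducts) if adducts is not None else list(chem.DEFAULT_ADDUCTS)
    parent = chem.parse_formula(parent_formula)
    out = []
    for rule in rules:
        product = rule.apply(parent)
        if product is None:
            warnings.warn(f"rule {rule.name!r} removes atoms absent from {parent_formula}; skipped")
            continue
        m = chem.monoisotopic_mass(product)
        out.append(
            BioTPCandidate(
                rule=rule.name,
                formula=chem.composition_to_formula(product),
                neutral_mass=m,
                expected_mz={a.name: a.mz(m) for a in adducts},
            )
        )
    return out


def match_features_ppm(
    features: pd.DataFrame, candidates: list[BioTPCandidate], tol_ppm: float = 5.0
) -> list[FeatureMatch]:
    """All (feature, candidate, adduct) triples within the ppm tolerance.

    `features` is a feature-metadata frame indexed by feature_id with an `mz`
    column. A feature may match several candidates.
    """
    if tol_ppm <= 0:
        raise ValueError("ppm tolerance must be positive")
    matches = []
    for fid, row in features.iterrows():
        mz = float(row["mz"])
        for cand in candidates:
            for adduct, expected in cand.expected_mz.items():
                ppm = chem.ppm_error(mz, expected)
                if abs(ppm) <= tol_ppm:
                    matches.append(FeatureMatch(str(fid), cand, adduct, mz, float(ppm)))
    return matches


def negative_control_filter(
    matches: list[FeatureMatch], table: FeatureTable
) -> list[FeatureMatch]:
    """Drop matches whose feature shows any signal in a negative-control embryo."""
    controls = table.samples_with_role("negative_control")
    if len(controls) == 0:
        raise ValueError("no negative-control samples in table")
    kept = []
    for m in matches:
        signal = bool((table.intensities.loc[m.feature_id, controls] > 0).any())
        m.in_negative_control = signal
        if not signal:
            kept.append(m)
    return kept


def score_against_library(
    match: FeatureMatch,
    spectrum: MS2Spectrum | None,
    library: list[MS2Spectrum],
    frag_tol: float = 0.01,
    precursor_tol_ppm: float = 10.0,
) -> FeatureMatch:
    """Score a feature's MS2 against reference spectra with matching precursor."""
    if spectrum is None or not spectrum.peaks:
        return match
    best, best_name = None, None
    for ref in library:
        if ref.precursor_mz > 0 and abs(
            chem.ppm_error(spectrum.precursor_mz, ref.precursor_mz)
        ) > precursor_tol_ppm:
            continue
        s = ms2_similarity(spectrum, ref, frag_tol)
        if best is None or s > best:
            best, best_name = s, ref.name
    match.best_similarity = best
    match.best_reference = best_name
    return match


def assign_confidence_level(evidence: EvidenceRecord, standard_cutoff: float = 0.9) -> int:
    """Map identification evidence to a confidence level.

    CL 1: similarity > 0.9 against an authentic-standard spectrum;
    CL 2: spectral-library score > 0.9; CL 3: a consistent structure
    prediction; CL 4: chemical formula consistent across spectra;
    CL 5: everything else (including features with no MS2 at all).
    """
    if not evidence.has_ms2:
        return 5
    if evidence.standard_similarity is not None and evidence.standard_similarity > standard_cutoff:
        return 1
    if evidence.library_score is not None and evidence.library_score > standard_cutoff:
        return 2
    if evidence.structure_predicted:
        return 3
    if evidence.formula_consistent:
        return 4
    return 5


def flag_insource_ambiguity(
    match: FeatureMatch,
    parent_feature_id: str,
    table: FeatureTable,
    rt_tol: float = 5.0,
    min_corr: float = 0.8,
) -> FeatureMatch:
    """Flag a candidate that cannot be distinguished from an in-source fragment
    of the exposure compound: it co-elutes with the parent and its intensity
    co-varies with the parent's across embryo samples."""
    if parent_feature_id not in table.feature_ids:
        raise ValueError(f"parent feature {parent_feature_id!r} not in table")
    if match.feature_id not in table.feature_ids:
        return match
    embryos = table.embryo_samples
    prt = float(table.features.loc[parent_feature_id, "rt_seconds"])
    frt = float(table.features.loc[match.feature_id, "rt_seconds"])
    if abs(frt - prt) > rt_tol:
        match.insource_ambiguous = False
        return match
    pvec = table.intensities.loc[parent_feature_id, embryos].to_numpy(float)
    fvec = table.intensities.loc[match.feature_id, embryos].to_numpy(float)
    if np.std(pvec) == 0 or np.std(fvec) == 0:
        return match
    r = float(np.corrcoef(pvec, fvec)[0, 1])
    match.insource_ambiguous = r >= min_corr
    return match


def dedupe_adducts(identified: list[tuple[str, str, str]]) -> list[str]:
    """Collapse adduct duplicates: (feature_id, compound, adduct) triples whose
    compound coincides map to one entry. A feature assigned to two different
    compounds is a conflict and raises."""
    by_feature: dict[str, str] = {}
    compounds: list[str] = []
    for fid, compound, _adduct in identified:
        if fid in by_feature and by_feature[fid] != compound:
            raise ValueError(
                f"feature {fid!r} assigned to both {by_feature[fid]!r} and {compound!r}"
            )
        by_feature[fid] = compound
        if compound not in compounds:
            compounds.append(compound)
    return compounds


# ---------------------------------------------------------------------------
# orchestration


@dataclass
class AnnotationConfig:
    parent_formula: str = chem.CBZ_FORMULA
    tol_ppm: float = 5.0
    frag_tol: float = 0.01
    similarity_cutoff: float = 0.9
    rt_tol: float = 5.0
    min_corr: float = 0.8


def annotate_biotps(
    raw_table: FeatureTable,
    spectra: dict[str, MS2Spectrum],
    library: list[MS2Spectrum],
    config: AnnotationConfig | None = None,
    rules: list[TransformationRule] | None = None,
    adducts: list[AdductRule] | None = None,
) -> pd.DataFrame:
    """Full bioTP workflow on the raw (pre-filter) feature table.

    Predict masses -> ppm matching (the exposure compound itself is excluded
    from the bioTP report) -> negative-control filter -> MS2 similarity against
    the reference library -> confidence levels -> in-source ambiguity flags.
    Returns a tidy candidate report.
    """
    config = config or AnnotationConfig()
    candidates = predict_biotp_masses(config.parent_formula, rules, adducts)
    parent_cand = [c for c in candidates if c.rule == "parent"]
    biotp_cands = [c for c in candidates if c.rule != "parent"]

    matches = match_features_ppm(raw_table.features, biotp_cands, config.tol_ppm)
    # locate the exposure compound itself for the ambiguity check
    parent_fid = None
    if parent_cand:
        pmatches = match_features_ppm(raw_table.features, parent_cand, config.tol_ppm)
        if pmatches:
            parent_fid = min(pmatches, key=lambda m: abs(m.ppm_error)).feature_id
    matches = [m for m in matches if m.feature_id != parent_fid]
    matches = negative_control_filter(matches, raw_table)

    rows = []
    for m in matches:
        sp = spectra.get(m.feature_id)
        m = score_against_library(m, sp, library, config.frag_tol)
        evidence = EvidenceRecord(
            standard_similarity=m.best_similarity,
            has_ms2=sp is not None and bool(sp.peaks),
        )
        m.confidence_level = assign_confidence_level(evidence, config.similarity_cutoff)
        if parent_fid is not None:
            m = flag_insource_ambiguity(m, parent_fid, raw_table, config.rt_tol, config.min_corr)
        rows.append(
            dict(
                feature_id=m.feature_id,
                rule=m.candidate.rule,
                formula=m.candidate.formula,
                adduct=m.adduct,
                expected_mz=m.candidate.expected_mz[m.adduct],
                observed_mz=m.observed_mz,
                ppm_error=m.ppm_error,
                has_ms2=m.feature_id in spectra,
                best_similarity=m.best_similarity,
                best_reference=m.best_reference,
                confidence_level=m.confidence_level,
                insource_ambiguous=m.insource_ambiguous,
            )
        )
    return pd.DataFrame(rows)
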