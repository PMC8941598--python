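"""Internal-standard normalization, QC drift correction, and the feature-filter
cascade that separates endogenous metabolite features from exposure-compound
signals, in-source fragments, blank contamination and drift artifacts.

Filter conventions (all threshold comparisons are strict, matching the printed
inequality directions of the underlying workflow):

(i)   qc_presence_filter   — drop features absent (zero) in every pooled-QC injection
(ii)  correct_drift + qc_rsd_filter — LOWESS over QC intensities vs injection
      order, divide through, rescale to the QC median; drop features whose
      post-correction QC RSD exceeds 30%
(iii) noise_floor_filter   — drop features whose maximum embryo intensity is
      below an absolute floor (default: 3x the median blank intensity)
(iv)  remove_insource_fragments — drop features co-eluting with the exposure
      compound, below its m/z, and correlated with it across samples
(v)   exclude_biotp_masses — drop features within 5 ppm of predicted
      biotransformation-product masses
(vi)  remove_negative_features — drop features driven negative by drift
      overcorrection
(vii) blank_fraction_filter — drop features whose blank (QC-blank) maximum
      exceeds 40% of the maximum sample (QC) intensity

The lipidomics assay instead uses a blank:negative-control ratio filter
(retain only ratio >= 10 control/blank).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from statsmodels.nonparametric.smoothers_lowess import lowess

from .containers import FeatureTable


# ---------------------------------------------------------------------------
# normalization


def normalize_to_is(table: FeatureTable, is_feature_ids: list[str]) -> FeatureTable:
    """Divide each sample's intensities by that sample's mean internal-standard
    intensity (scaled back to the grand mean so units stay comparable)."""
    missing = [f for f in is_feature_ids if f not in table.feature_ids]
    if missing:
        raise ValueError(f"internal-standard features not in table: {missing}")
    is_block = table.intensities.loc[is_feature_ids]
    per_sample = is_block.mean(axis=0)
    bad = per_sample.index[(per_sample <= 0) | per_sample.isna()]
    if len(bad):
        raise ValueError(f"zero or missing internal standard in samples: {list(bad)}")
    factors = per_sample / per_sample.mean()
    out = table.copy()
    out.intensities = table.intensities.div(factors, axis=1)
    out.note_step("is_normalization")
    return out


# ---------------------------------------------------------------------------
# drift correction


@dataclass
class DriftModel:
    """Per-feature QC-anchored correction curves over injection order."""

    qc_indices: np.ndarray  # injection indices of QC anchors
    curves: pd.DataFrame  # features x all injection indices: fitted curve values
    qc_rsd_before: pd.Series  # % RSD over QC injections pre-correction
    qc_rsd_after: pd.Series  # % RSD post-correction (NaN for uncorrectable features)
    uncorrectable: list[str] = field(default_factory=list)


def _fit_qc_curve(qc_x: np.ndarray, qc_y: np.ndarray, all_x: np.ndarray) -> np.ndarray:
    """Smooth curve through QC points evaluated at every injection index.

    Locally weighted regression when >= 5 QC anchors, otherwise linear
    interpolation; flat extrapolation beyond the first/last QC.
    """
    if len(qc_x) >= 5:
        fitted = lowess(qc_y, qc_x, frac=min(1.0, 5.0 / len(qc_x) + 0.3), it=0,
                        return_sorted=True)
        xs, ys = fitted[:, 0], fitted[:, 1]
    else:
        xs, ys = qc_x, qc_y
    return np.interp(all_x, xs, ys)


def correct_drift(table: FeatureTable) -> tuple[FeatureTable, DriftModel]:
    """Fit a smooth QC-intensity curve per feature and divide it out.

    Each sample intensity is divided by the curve value at its injection index
    and rescaled to the feature's QC median. Features whose fitted curve is
    nonpositive anywhere are flagged and left uncorrected.
    """
    qc = table.qc_samples
    if len(qc) < 3:
        raise ValueError(f"drift correction needs >= 3 QC injections, found {len(qc)}")
    inj = table.samples["injection_index"].to_numpy(float)
    qc_x = table.samples.loc[qc, "injection_index"].to_numpy(float)
    order = np.argsort(qc_x)
    qc_x = qc_x[order]
    qc_cols = qc[order]

    X = table.intensities.to_numpy(float)
    qc_block = table.intensities[qc_cols].to_numpy(float)

    def rsd(mat: np.ndarray) -> np.ndarray:
        mean = mat.mean(axis=1)
        sd = mat.std(axis=1, ddof=1)
        with np.errstate(divide="ignore", invalid="ignore"):
            out = 100.0 * sd / mean
        return out

    rsd_before = pd.Series(rsd(qc_block), index=table.feature_ids)

    corrected = X.copy()
    curves = np.ones((X.shape[0], len(inj)))
    uncorrectable: list[str] = []
    for i, fid in enumerate(table.feature_ids):
        y = qc_block[i]
        curve = _fit_qc_curve(qc_x, y, inj)
        curves[i] = curve
        if np.any(curve <= 0):
            uncorrectable.append(str(fid))
            continue
        qc_median = float(np.median(y))
        corrected[i] = X[i] / curve * qc_median

    out = table.copy()
    out.intensities = pd.DataFrame(corrected, index=table.feature_ids, columns=table.sample_ids)
    if "drift_uncorrectable" not in out.features.columns:
        out.features["drift_uncorrectable"] = False
    out.features.loc[out.features.index.isin(uncorrectable), "drift_uncorrectable"] = True

    qc_after = out.intensities[qc_cols].to_numpy(float)
    rsd_after = pd.Series(rsd(qc_after), index=table.feature_ids)
    rsd_after[rsd_after.index.isin(uncorrectable)] = np.nan

    model = DriftModel(
        qc_indices=qc_x,
        curves=pd.DataFrame(curves, index=table.feature_ids, columns=table.sample_ids),
        qc_rsd_before=rsd_before,
        qc_rsd_after=rsd_after,
        uncorrectable=uncorrectable,
    )
    out.note_step("drift_correction", flagged=uncorrectable)
    return out, model


# ---------------------------------------------------------------------------
# individual filters


def qc_presence_filter(table: FeatureTable) -> FeatureTable:
    """Step (i): remove features with zero/missing intensity in all QC injections.

    Presence means any nonzero intensity in at least one QC injection."""
    qc = table.qc_samples
    if len(qc) == 0:
        raise ValueError("no QC samples in table")
    block = table.intensities[qc]
    absent = table.feature_ids[(block.fillna(0) == 0).all(axis=1)]
    return table.drop_features(absent, "qc_presence_filter", flag="qc_absent")


def qc_rsd_filter(table: FeatureTable, model: DriftModel, threshold: float = 30.0) -> FeatureTable:
    """Step (ii): remove features whose post-correction QC RSD exceeds the
    threshold (%); RSD = 100*sd/mean over QC injections."""
    if threshold <= 0:
        raise ValueError("RSD threshold must be positive")
    rsd = model.qc_rsd_after.reindex(table.feature_ids)
    bad = table.feature_ids[(rsd > threshold) | rsd.isna()]
    return table.drop_features(bad, "qc_rsd_filter", flag="high_rsd")


def noise_floor_filter(table: FeatureTable, floor: float | None = None) -> FeatureTable:
    """Step (iii): remove features whose maximum embryo intensity is below an
    absolute intensity floor (default 3x the median blank intensity)."""
    if floor is None:
        blanks = table.blank_samples
        floor = 3.0 * float(np.median(table.intensities[blanks].to_numpy())) if len(blanks) else 0.0
    embryos = table.embryo_samples
    max_embryo = table.intensities[embryos].max(axis=1)
    bad = table.feature_ids[max_embryo < floor]
    return table.drop_features(bad, "noise_floor_filter", flag="below_noise_floor")


def remove_insource_fragments(
    table: FeatureTable,
    parent_feature_id: str | None = None,
    rt_tol: float = 5.0,
    min_corr: float = 0.8,
    parent_mz: float | None = None,
    parent_rt: float | None = None,
    parent_profile: pd.Series | None = None,
) -> FeatureTable:
    """Step (iv): remove putative in-source fragments of the exposure compound.

    A fragment co-elutes with the parent (|rt - parent rt| <= rt_tol), has a
    lower m/z, and its intensity correlates with the parent's (Pearson r >=
    min_corr) across embryo samples. The parent may be given as a feature id in
    the table or, when it was itself already filtered out, as an explicit
    (m/z, rt, intensity profile) triple.
    """
    if parent_feature_id is not None:
        if parent_feature_id not in table.feature_ids:
            raise ValueError(f"parent feature {parent_feature_id!r} not present in table")
        parent_mz = float(table.features.loc[parent_feature_id, "mz"])
        parent_rt = float(table.features.loc[parent_feature_id, "rt_seconds"])
        parent_profile = table.intensities.loc[parent_feature_id]
    if parent_mz is None or parent_rt is None or parent_profile is None:
        raise ValueError("parent m/z, rt and intensity profile are required")
    embryos = table.embryo_samples
    pvec = parent_profile.loc[embryos].to_numpy(float)
    if np.std(pvec) == 0:
        return table.drop_features([], "insource_fragment_filter", flag="insource")
    bad = []
    for fid in table.feature_ids:
        if fid == parent_feature_id:
            continue
        meta = table.features.loc[fid]
        if meta["mz"] >= parent_mz or abs(meta["rt_seconds"] - parent_rt) > rt_tol:
            continue
        v = table.intensities.loc[fid, embryos].to_numpy(float)
        if np.std(v) == 0:
            continue
        r = float(np.corrcoef(pvec, v)[0, 1])
        if r >= min_corr:
            bad.append(fid)
    return table.drop_features(bad, "insource_fragment_filter", flag="insource")


def exclude_biotp_masses(
    table: FeatureTable, predicted_masses: list[float], tol_ppm: float = 5.0
) -> FeatureTable:
    """Step (v): remove features within tol_ppm of any predicted bioTP m/z."""
    if tol_ppm <= 0:
        raise ValueError("ppm tolerance must be positive")
    if not predicted_masses:
        raise ValueError("predicted mass list is empty")
    mz = table.features["mz"].to_numpy(float)
    hit = np.zeros(len(mz), dtype=bool)
    for m in predicted_masses:
        hit |= np.abs(mz - m) / m * 1e6 <= tol_ppm
    bad = table.feature_ids[hit]
    return table.drop_features(bad, "biotp_mass_exclusion", flag="biotp_mass_match")


def remove_negative_features(table: FeatureTable) -> FeatureTable:
    """Step (vi): remove features with any negative intensity in embryo samples
    (drift overcorrection artifacts); zeros are kept (zero = non-detection)."""
    embryos = table.embryo_samples
    bad = table.feature_ids[(table.intensities[embryos] < 0).any(axis=1)]
    return table.drop_features(bad, "negative_intensity_filter", flag="negative_intensity")


def blank_fraction_filter(table: FeatureTable, fraction: float = 0.40) -> FeatureTable:
    """Step (vii): remove features whose maximum blank intensity exceeds
    `fraction` of the maximum sample intensity, or whose maximum QC-blank
    intensity exceeds `fraction` of the maximum QC intensity."""
    blanks = table.blank_samples
    qc_blanks = table.qc_blank_samples
    if len(blanks) == 0 and len(qc_blanks) == 0:
        out = table.copy()
        out.note_step("blank_fraction_filter (skipped: no blanks)")
        return out
    embryos = table.embryo_samples
    qc = table.qc_samples
    bad = pd.Series(False, index=table.feature_ids)
    if len(blanks) and len(embryos):
        bad |= table.intensities[blanks].max(axis=1) > fraction * table.intensities[embryos].max(axis=1)
    if len(qc_blanks) and len(qc):
        bad |= table.intensities[qc_blanks].max(axis=1) > fraction * table.intensities[qc].max(axis=1)
    return table.drop_features(table.feature_ids[bad], "blank_fraction_filter", flag="blank_dominated")


def lipid_blank_ratio_filter(table: FeatureTable, min_ratio: float = 10.0) -> FeatureTable:
    """Lipidomics filter: retain a feature only when mean negative-control
    intensity / mean blank intensity >= min_ratio (zero blank = infinite ratio,
    retained)."""
    blanks = table.blank_samples
    controls = table.samples_with_role("negative_control")
    if len(blanks) == 0 or len(controls) == 0:
        raise ValueError("blank and negative-control samples are required")
    blank_mean = table.intensities[blanks].mean(axis=1)
    ctrl_mean = table.intensities[controls].mean(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = ctrl_mean / blank_mean
    ratio[blank_mean == 0] = np.inf
    bad = table.feature_ids[ratio < min_ratio]
    return table.drop_features(bad, "lipid_blank_ratio_filter", flag="low_blank_ratio")


# ---------------------------------------------------------------------------
# cascade


@dataclass
class CascadeConfig:
    """Parameters of the endogenous-feature filter cascade."""

    rsd_threshold: float = 30.0
    noise_floor: float | None = None  # None -> 3x median blank intensity
    rt_tol: float = 5.0
    min_corr: float = 0.8
    biotp_tol_ppm: float = 5.0
    blank_fraction: float = 0.40
    lipid_min_ratio: float = 10.0
    parent_mz: float | None = None  # exposure-compound [M+H] m/z
    parent_rt: float | None = None
    predicted_biotp_masses: list[float] = field(default_factory=list)


def _locate_parent(table: FeatureTable, config: CascadeConfig):
    """Find the exposure-compound feature in the raw table by m/z (+rt)."""
    if config.parent_mz is None:
        return None
    mz = table.features["mz"].to_numpy(float)
    ppm = np.abs(mz - config.parent_mz) / config.parent_mz * 1e6
    cand = np.flatnonzero(ppm <= config.biotp_tol_ppm)
    if cand.size == 0:
        return None
    if config.parent_rt is not None and cand.size > 1:
        rts = table.features["rt_seconds"].to_numpy(float)[cand]
        cand = cand[[int(np.argmin(np.abs(rts - config.parent_rt)))]]
    fid = table.feature_ids[cand[0]]
    return (
        float(table.features.loc[fid, "mz"]),
        float(table.features.loc[fid, "rt_seconds"]),
        table.intensities.loc[fid],
    )


def run_filter_cascade(
    table: FeatureTable, config: CascadeConfig | None = None
) -> tuple[FeatureTable, list]:
    """Apply the full endogenous-feature filter cascade.

    Nontarget features pass steps (i)-(vii) in order; lipidomics features pass
    the blank:control ratio filter. The exposure-compound intensity profile for
    step (iv) is taken from the input table (the compound itself is removed at
    step (i), being absent from the QC). Returns the filtered table and its
    audit trail.
    """
    config = config or CascadeConfig()
    parent = _locate_parent(table, config)

    assays = table.features["assay"]
    nt_ids = table.feature_ids[assays == "nontarget"]
    lp_ids = table.feature_ids[assays == "lipidomics"]

    def subset(ids) -> FeatureTable:
        return FeatureTable(
            table.intensities.loc[ids], table.features.loc[ids], table.samples.copy()
        )

    # --- nontarget cascade --------------------------------------------------
    nt = subset(nt_ids)
    nt = qc_presence_filter(nt)  # (i)
    nt, model = correct_drift(nt)  # (ii)
    nt = qc_rsd_filter(nt, model, config.rsd_threshold)
    nt = noise_floor_filter(nt, config.noise_floor)  # (iii)
    if parent is not None:  # (iv)
        pmz, prt, pprof = parent
        nt = remove_insource_fragments(
            nt, rt_tol=config.rt_tol, min_corr=config.min_corr,
            parent_mz=pmz, parent_rt=prt, parent_profile=pprof,
        )
    else:
        nt.note_step("insource_fragment_filter (skipped: no parent)")
    if config.predicted_biotp_masses:  # (v)
        nt = exclude_biotp_masses(nt, config.predicted_biotp_masses, config.biotp_tol_ppm)
    else:
        nt.note_step("biotp_mass_exclusion (skipped: no mass list)")
    nt = remove_negative_features(nt)  # (vi)
    nt = blank_fraction_filter(nt, config.blank_fraction)  # (vii)

    # --- lipidomics ratio filter ---------------------------------------------
    if len(lp_ids):
        lp = subset(lp_ids)
        lp = lipid_blank_ratio_filter(lp, config.lipid_min_ratio)
        keep = nt.feature_ids.append(lp.feature_ids)
        audit = nt.audit + lp.audit
    else:
        keep = nt.feature_ids
        audit = nt.audit

    intensities = pd.concat(
        [nt.intensities] + ([lp.intensities] if len(lp_ids) else []), axis=0
    )
    features = pd.concat([nt.features] + ([lp.features] if len(lp_ids) else []), axis=0)
    out = FeatureTable(intensities.loc[keep], features.loc[keep], table.samples.copy(), audit)
    return out, audit
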