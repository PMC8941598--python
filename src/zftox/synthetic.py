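"""Synthetic single-embryo toxicometabolomics study generator.

Emulates a 96-well-plate zebrafish embryo exposure to carbamazepine (CBZ):
six nominal doses (0.5 ug/L .. 50 mg/L) x 12 embryos, 12 negative and 12
positive controls, a concurrent blank plate, pooled-embryo QC injections every
k-th injection, injection-order signal drift, multiplicative lognormal noise,
and a feature population with known ground truth: endogenous features (null and
six dose-response shapes), features absent from the QC, blank contaminants,
the exposure compound itself, its in-source fragments, and biotransformation
products (bioTPs) placed at rule-predicted m/z values.

Every downstream stage (filter cascade, rdCV models, bioTP annotation,
endpoint summaries) is testable against the returned :class:`SimTruth`.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import chem
from .containers import (
    FeatureTable,
    ROLE_BLANK,
    ROLE_DOSE,
    ROLE_NEG,
    ROLE_POS,
    ROLE_QC,
    ROLE_QC_BLANK,
)
from .spectra import MS2Spectrum

SHAPES = (
    "monotonic_up",
    "monotonic_down",
    "u_shape",
    "inverted_u",
    "high_dose_only",
    "edema_marker",
)

LABELS = (
    "endogenous_null",
    "endogenous_effect",
    "exogenous_parent",
    "insource_fragment",
    "biotp",
    "blank_contaminant",
    "qc_absent",
    "internal_standard",
)

# nominal exposure ladder (ug/L): 0.5 ug/L up to 50 mg/L in 10x steps
DEFAULT_NOMINAL_DOSES = (0.5, 5.0, 50.0, 500.0, 5000.0, 50000.0)

_ROWS = "ABCDEFGH"


@dataclass(frozen=True)
class PlateLayout:
    """Assignment of 96-well-plate wells to dose groups and controls."""

    wells: tuple[str, ...]
    assignments: dict  # well -> role string ("dose_1".."dose_n", negative_control, positive_control)
    nominal_doses: dict  # dose group index (1-based) -> concentration ug/L

    def group_wells(self, role: str) -> list[str]:
        return [w for w in self.wells if self.assignments[w] == role]


def all_wells() -> list[str]:
    return [f"{r}{c}" for r in _ROWS for c in range(1, 13)]


def make_plate_layout(
    n_doses: int,
    n_per_dose: int,
    n_neg: int,
    n_pos: int,
    nominal_doses: tuple[float, ...] | None = None,
) -> PlateLayout:
    """Deterministic column-major assignment of groups to a 96-well plate."""
    total = n_doses * n_per_dose + n_neg + n_pos
    if total > 96:
        raise ValueError(
            f"plate capacity exceeded: {n_doses}x{n_per_dose} + {n_neg} + {n_pos} "
            f"= {total} wells > 96"
        )
    if nominal_doses is None:
        nominal_doses = DEFAULT_NOMINAL_DOSES[:n_doses]
    if len(nominal_doses) != n_doses:
        raise ValueError("one nominal dose per dose group required")
    wells = all_wells()
    roles = []
    for g in range(1, n_doses + 1):
        roles.extend([f"dose_{g}"] * n_per_dose)
    roles.extend([ROLE_NEG] * n_neg)
    roles.extend([ROLE_POS] * n_pos)
    assigned = wells[: len(roles)]
    return PlateLayout(
        wells=tuple(assigned),
        assignments=dict(zip(assigned, roles)),
        nominal_doses={g + 1: float(d) for g, d in enumerate(nominal_doses)},
    )


@dataclass
class SimConfig:
    """Study-design parameters for the simulator.

    Defaults mirror the emulated exposure study: six doses x 12 embryos,
    12 negative + 12 positive controls, QC every 5th injection, a blank plate,
    mortality concentrated in the positive controls, and pericardial edema in
    the top dose group.
    """

    seed: int  # mandatory for reproducibility
    n_doses: int = 6
    n_per_group: int = 12
    n_neg: int = 12
    n_pos: int = 12
    nominal_doses: tuple[float, ...] = DEFAULT_NOMINAL_DOSES
    qc_every_k: int = 5
    n_blanks: int = 8
    n_qc_blanks: int = 3
    # feature population (nontarget assay)
    n_null: int = 150
    n_effect_per_shape: int = 5
    n_qc_absent: int = 20
    n_blank_contaminant: int = 20
    n_insource: int = 3
    n_biotp: int = 12
    # feature population (lipidomics assay)
    n_lipid_null: int = 90
    n_lipid_effect: int = 12
    n_lipid_low_ratio: int = 18
    # effect / noise / drift model
    effect_fold: float = 4.0
    noise_cv: float = 0.10
    loading_cv: float = 0.15
    drift: str = "linear"  # linear | exponential | none
    drift_magnitude: float = 0.5
    # apical endpoints: counts per group
    n_dead: dict = field(default_factory=lambda: {"positive_control": 11, "dose_3": 3, "dose_4": 1})
    n_edema: dict = field(default_factory=lambda: {"dose_6": 5, "dose_1": 1, "positive_control": 1})
    # hatched at 48 hpf per group (delayed in the three lower-dose groups)
    n_hatched: dict = field(
        default_factory=lambda: {
            "negative_control": 11,
            "positive_control": 10,
            "dose_1": 5,
            "dose_2": 5,
            "dose_3": 10,
            "dose_4": 5,
            "dose_5": 10,
            "dose_6": 10,
        }
    )
    parent_formula: str = chem.CBZ_FORMULA
    parent_rt: float = 420.0
    rt_range: tuple[float, float] = (60.0, 900.0)
    mz_range: tuple[float, float] = (85.0, 900.0)

    def __post_init__(self) -> None:
        if self.seed is None:
            raise ValueError("SimConfig.seed is mandatory")
        if self.qc_every_k < 2:
            raise ValueError("qc_every_k must be >= 2")
        if self.noise_cv < 0:
            raise ValueError("noise CV must be >= 0")
        if self.drift not in ("linear", "exponential", "none"):
            raise ValueError(f"unknown drift model: {self.drift!r}")


@dataclass
class SimTruth:
    """Per-feature ground-truth labels for the simulated table."""

    labels: pd.DataFrame  # index feature_id; columns label, shape, effect_size, drift_slope, parent_id, rule, adduct

    def ids_with_label(self, *labels: str) -> list[str]:
        return list(self.labels.index[self.labels["label"].isin(labels)])

    @property
    def endogenous_ids(self) -> list[str]:
        return self.ids_with_label("endogenous_null", "endogenous_effect")

    def label_counts(self) -> dict:
        return self.labels["label"].value_counts().to_dict()

    def to_json(self, path: str | Path) -> None:
        records = {
            fid: {k: (None if pd.isna(v) else v) for k, v in row.items()}
            for fid, row in self.labels.to_dict(orient="index").items()
        }
        Path(path).write_text(json.dumps(records, indent=1))

    @classmethod
    def from_json(cls, path: str | Path) -> "SimTruth":
        records = json.loads(Path(path).read_text())
        df = pd.DataFrame.from_dict(records, orient="index")
        df.index.name = "feature_id"
        return cls(df)


# ---------------------------------------------------------------------------
# dose-response shapes


def response_factor(
    shape: str,
    dose: float,
    fold: float,
    doses: tuple[float, ...],
    edema: bool = False,
) -> float:
    """Multiplicative response at a given nominal dose (controls: dose = 0).

    Monotone shapes are linear in log10(dose) between 1 and `fold`; U and
    inverted-U are quadratic in log10(dose) with the extremum at the middle
    dose; high_dose_only is a step at the top dose; edema_marker applies the
    fold change to edema-flagged embryos only. Responses are clipped to
    [1/fold, fold].
    """
    if shape not in SHAPES:
        raise ValueError(f"unknown dose-response shape: {shape!r}")
    lo, hi = math.log10(doses[0]), math.log10(doses[-1])
    if shape == "edema_marker":
        return fold if edema else 1.0
    if dose <= 0:
        # unexposed embryos: the low-exposure limit of the curve (the monotone
        # shapes are anchored at 1 there, the quadratic shapes at their arm value)
        x = lo
    else:
        x = math.log10(dose)
    if shape == "monotonic_up":
        t = (x - lo) / (hi - lo)
        r = 1.0 + (fold - 1.0) * max(t, 0.0)
    elif shape == "monotonic_down":
        t = (x - lo) / (hi - lo)
        r = 1.0 / (1.0 + (fold - 1.0) * max(t, 0.0))
    elif shape == "u_shape":
        mid = 0.5 * (lo + hi)
        t = (x - mid) / (hi - mid)
        r = 1.0 + (fold - 1.0) * t * t
    elif shape == "inverted_u":
        mid = 0.5 * (lo + hi)
        t = (x - mid) / (hi - mid)
        r = 1.0 + (fold - 1.0) * (1.0 - t * t)
    elif shape == "high_dose_only":
        r = fold if dose >= doses[-1] else 1.0
    return float(min(max(r, 1.0 / fold), fold))


def _drift_curve(kind: str, slope: float, idx: np.ndarray, n_total: int) -> np.ndarray:
    t = (idx - 1) / max(n_total - 1, 1)
    if kind == "linear":
        return 1.0 + slope * t
    if kind == "exponential":
        return np.exp(slope * t)
    return np.ones_like(t, dtype=float)


# ---------------------------------------------------------------------------
# sample bookkeeping


def _assign_endpoints(samples: pd.DataFrame, config: SimConfig, rng: np.random.Generator) -> None:
    for col in ("dead_120hpf", "edema", "hatched_48hpf"):
        samples[col] = pd.NA
    embryos = samples.index[samples["role"].isin((ROLE_DOSE, ROLE_NEG, ROLE_POS))]
    samples.loc[embryos, ["dead_120hpf", "edema"]] = False
    samples.loc[embryos, "hatched_48hpf"] = True
    for group, counts in (
        (config.n_dead, "dead_120hpf"),
        (config.n_edema, "edema"),
    ):
        for gname, n in group.items():
            members = [s for s in embryos if samples.loc[s, "group"] == gname]
            chosen = rng.choice(members, size=min(n, len(members)), replace=False)
            samples.loc[chosen, counts] = True
    for gname, n_hatch in config.n_hatched.items():
        members = [s for s in embryos if samples.loc[s, "group"] == gname]
        if not members:
            continue
        not_hatched = rng.choice(members, size=max(len(members) - n_hatch, 0), replace=False)
        samples.loc[not_hatched, "hatched_48hpf"] = False


def build_sample_metadata(layout: PlateLayout, config: SimConfig) -> pd.DataFrame:
    """Sample records with injection order: QC bracketing every k-th injection."""
    rng = np.random.default_rng(config.seed)
    rows = []
    for well in layout.wells:
        role = layout.assignments[well]
        if role.startswith("dose_"):
            g = int(role.split("_")[1])
            rows.append(
                dict(sample_id=f"D{g}_{well}", well=well, role=ROLE_DOSE, group=role,
                     dose_group=g, nominal_dose=layout.nominal_doses[g])
            )
        elif role == ROLE_NEG:
            rows.append(dict(sample_id=f"NC_{well}", well=well, role=ROLE_NEG, group=role,
                             dose_group=0, nominal_dose=0.0))
        else:
            rows.append(dict(sample_id=f"PC_{well}", well=well, role=ROLE_POS, group=role,
                             dose_group=-1, nominal_dose=np.nan))
    for b in range(1, config.n_blanks + 1):
        rows.append(dict(sample_id=f"BL_{b:02d}", well=f"BP{b:02d}", role=ROLE_BLANK,
                         group="blank", dose_group=-1, nominal_dose=np.nan))
    analytical = [r["sample_id"] for r in rows]
    order = rng.permutation(len(analytical))
    injection_seq: list[str] = []
    qc_counter = 0

    def next_qc() -> str:
        nonlocal qc_counter
        qc_counter += 1
        return f"QC_{qc_counter:02d}"

    injection_seq.append(next_qc())
    for pos, k in enumerate(order, start=1):
        injection_seq.append(analytical[k])
        if pos % (config.qc_every_k - 1) == 0:
            injection_seq.append(next_qc())
    if not injection_seq[-1].startswith("QC_"):
        injection_seq.append(next_qc())
    for qb in range(1, config.n_qc_blanks + 1):
        injection_seq.append(f"QB_{qb:02d}")

    for q in range(1, qc_counter + 1):
        rows.append(dict(sample_id=f"QC_{q:02d}", well="", role=ROLE_QC, group="qc",
                         dose_group=-1, nominal_dose=np.nan))
    for qb in range(1, config.n_qc_blanks + 1):
        rows.append(dict(sample_id=f"QB_{qb:02d}", well="", role=ROLE_QC_BLANK,
                         group="qc_blank", dose_group=-1, nominal_dose=np.nan))

    samples = pd.DataFrame(rows).set_index("sample_id")
    samples["injection_index"] = 0
    for idx, sid in enumerate(injection_seq, start=1):
        samples.loc[sid, "injection_index"] = idx
    samples = samples.loc[injection_seq]
    _assign_endpoints(samples, config, rng)
    return samples


# ---------------------------------------------------------------------------
# feature table simulation


def predicted_biotp_mzs(config: SimConfig) -> list[tuple[str, str, float]]:
    """(rule, adduct, expected m/z) for the built-in transformation library."""
    parent = chem.parse_formula(config.parent_formula)
    out = []
    for rule in chem.DEFAULT_RULES:
        product = rule.apply(parent)
        if product is None:
            continue
        m = chem.monoisotopic_mass(product)
        for adduct in chem.DEFAULT_ADDUCTS:
            out.append((rule.name, adduct.name, adduct.mz(m)))
    return out


def simulate_feature_table(layout: PlateLayout, config: SimConfig) -> tuple[FeatureTable, SimTruth]:
    """Simulate the combined lipidomics + nontarget feature table.

    Intensity model per measurement:
    ``baseline * response(shape, dose) * drift(injection) * loading * lognormal noise``
    with label-specific presence/absence (exogenous features absent in QC and
    controls, blank contaminants high in blanks, qc_absent features zeroed in
    QC injections). Identical (layout, config) give bit-identical output.
    """
    rng = np.random.default_rng(config.seed + 1)
    samples = build_sample_metadata(layout, config)
    n_inj = int(samples["injection_index"].max())
    inj = samples["injection_index"].to_numpy(float)
    roles = samples["role"].to_numpy()
    doses = samples["nominal_dose"].to_numpy(float)
    edema = (samples["edema"] == True).to_numpy()  # noqa: E712 (NA -> False)

    is_qc = roles == ROLE_QC
    is_blank = roles == ROLE_BLANK
    is_qc_blank = roles == ROLE_QC_BLANK
    is_embryo = np.isin(roles, (ROLE_DOSE, ROLE_NEG, ROLE_POS))
    is_dosed = roles == ROLE_DOSE

    loading = np.ones(len(samples))
    if config.loading_cv > 0:
        sigma = math.sqrt(math.log(1 + config.loading_cv**2))
        loading = rng.lognormal(-0.5 * sigma**2, sigma, size=len(samples))
    # blanks/QC blanks carry solvent, not embryo matrix: loading applies to all
    # injections (it models injection/extraction scale, spiked IS follows it).

    parent_mz = chem.DEFAULT_ADDUCTS[0].mz(chem.monoisotopic_mass(config.parent_formula))
    # adduct-major order so every transformation appears as [M+H] before any
    # second adduct is simulated
    _biotps = [t for t in predicted_biotp_mzs(config) if t[0] != "parent"]
    _adduct_order = [a.name for a in chem.DEFAULT_ADDUCTS]
    biotp_list = sorted(_biotps, key=lambda t: (_adduct_order.index(t[1]), _biotps.index(t)))
    predicted_all = [mz for _, _, mz in predicted_biotp_mzs(config)]

    def random_mz(n: int) -> np.ndarray:
        """Endogenous m/z values kept > 20 ppm away from any predicted bioTP mass."""
        out = np.empty(n)
        filled = 0
        while filled < n:
            cand = rng.uniform(*config.mz_range, size=n - filled)
            ok = np.ones(len(cand), bool)
            for m in predicted_all:
                ok &= np.abs(cand - m) / m * 1e6 > 20.0
            took = cand[ok]
            out[filled : filled + len(took)] = took
            filled += len(took)
        return out

    def random_rt(n: int) -> np.ndarray:
        """Retention times excluding a guard window around the parent."""
        out = np.empty(n)
        filled = 0
        while filled < n:
            cand = rng.uniform(*config.rt_range, size=n - filled)
            took = cand[np.abs(cand - config.parent_rt) > 15.0]
            out[filled : filled + len(took)] = took
            filled += len(took)
        return out

    feature_rows = []  # (fid, mz, rt, assay, label, shape, effect, parent_id, rule, adduct)
    intensity_rows = []
    noise_sigma = math.sqrt(math.log(1 + config.noise_cv**2)) if config.noise_cv > 0 else 0.0

    def noise(n: int) -> np.ndarray:
        if noise_sigma == 0:
            return np.ones(n)
        return rng.lognormal(-0.5 * noise_sigma**2, noise_sigma, size=n)

    def drift_for(slope: float) -> np.ndarray:
        return _drift_curve(config.drift, slope, inj, n_inj)

    counter = {"nt": 0, "lp": 0}

    def add_feature(assay, label, base_profile, mz, rt, shape=None, effect=np.nan,
                    parent_id=None, rule=None, adduct=None, drift_slope=None):
        prefix = "nt" if assay == "nontarget" else "lp"
        counter[prefix] += 1
        fid = f"{prefix}_{counter[prefix]:04d}"
        if drift_slope is None:
            drift_slope = float(rng.uniform(-config.drift_magnitude, config.drift_magnitude))
        vec = base_profile * drift_for(drift_slope) * loading * noise(len(samples))
        feature_rows.append((fid, mz, rt, assay, label, shape, effect, parent_id, rule, adduct, drift_slope))
        intensity_rows.append(vec)
        return fid

    def baseline() -> float:
        return float(10 ** rng.uniform(5.0, 7.0))

    def endogenous_profile(shape: str | None, fold: float) -> np.ndarray:
        base = baseline()
        prof = np.full(len(samples), base)
        if shape is not None:
            for i in range(len(samples)):
                if is_embryo[i]:
                    d = doses[i] if is_dosed[i] else 0.0
                    prof[i] = base * response_factor(shape, d, fold, config.nominal_doses, edema[i])
                elif is_qc[i]:
                    prof[i] = base  # pooled QC at baseline level
        prof[is_blank | is_qc_blank] = 0.0
        return prof

    # --- nontarget assay ---------------------------------------------------
    # internal standard: constant level, present in every injection
    is_base = baseline()
    add_feature("nontarget", "internal_standard",
                np.full(len(samples), is_base), random_mz(1)[0], random_rt(1)[0],
                drift_slope=0.0)

    mzs = random_mz(config.n_null)
    rts = random_rt(config.n_null)
    for i in range(config.n_null):
        add_feature("nontarget", "endogenous_null", endogenous_profile(None, 1.0), mzs[i], rts[i])

    for shape in SHAPES:
        mzs = random_mz(config.n_effect_per_shape)
        rts = random_rt(config.n_effect_per_shape)
        for i in range(config.n_effect_per_shape):
            add_feature("nontarget", "endogenous_effect",
                        endogenous_profile(shape, config.effect_fold),
                        mzs[i], rts[i], shape=shape, effect=config.effect_fold)

    mzs = random_mz(config.n_qc_absent)
    rts = random_rt(config.n_qc_absent)
    for i in range(config.n_qc_absent):
        prof = endogenous_profile(None, 1.0)
        prof[is_qc] = 0.0
        add_feature("nontarget", "qc_absent", prof, mzs[i], rts[i])

    mzs = random_mz(config.n_blank_contaminant)
    rts = random_rt(config.n_blank_contaminant)
    for i in range(config.n_blank_contaminant):
        base = baseline()
        prof = np.full(len(samples), base)  # procedural background: everywhere, blanks included
        add_feature("nontarget", "blank_contaminant", prof, mzs[i], rts[i])

    # exposure compound: proportional to dose, absent in QC, controls and blanks
    parent_scale = 1e6 / config.nominal_doses[-1]
    prof = np.where(is_dosed, np.nan_to_num(doses) * parent_scale, 0.0)
    parent_id = add_feature("nontarget", "exogenous_parent", prof, parent_mz,
                            config.parent_rt)

    # in-source fragments of the parent: co-eluting, lower m/z, co-varying
    for i in range(config.n_insource):
        frac = 0.6 - 0.15 * i
        add_feature("nontarget", "insource_fragment", prof * frac,
                    parent_mz - 18.0 * (i + 1) - rng.uniform(0, 5),
                    config.parent_rt, parent_id=parent_id)

    # bioTPs at rule-predicted m/z (small ppm offset), dose-proportional,
    # absent in QC/controls/blanks
    chosen = biotp_list[: config.n_biotp]
    for k, (rule, adduct, mz_exp) in enumerate(chosen):
        ppm_off = rng.uniform(-4.0, 4.0)
        mz_obs = mz_exp * (1 + ppm_off * 1e-6)
        rt = config.parent_rt if rule == "carbamoyl_loss" else random_rt(1)[0]
        scale = parent_scale * rng.uniform(0.01, 0.1)
        add_feature("nontarget", "biotp", prof / parent_scale * scale, mz_obs, rt,
                    parent_id=parent_id, rule=rule, adduct=adduct)

    # --- lipidomics assay ---------------------------------------------------
    add_feature("lipidomics", "internal_standard",
                np.full(len(samples), baseline()), random_mz(1)[0], random_rt(1)[0],
                drift_slope=0.0)
    mzs = random_mz(config.n_lipid_null)
    rts = random_rt(config.n_lipid_null)
    for i in range(config.n_lipid_null):
        add_feature("lipidomics", "endogenous_null", endogenous_profile(None, 1.0), mzs[i], rts[i])
    lipid_shapes = ("monotonic_up", "monotonic_down", "inverted_u")
    mzs = random_mz(config.n_lipid_effect)
    rts = random_rt(config.n_lipid_effect)
    for i in range(config.n_lipid_effect):
        shape = lipid_shapes[i % len(lipid_shapes)]
        add_feature("lipidomics", "endogenous_effect",
                    endogenous_profile(shape, config.effect_fold), mzs[i], rts[i],
                    shape=shape, effect=config.effect_fold)
    mzs = random_mz(config.n_lipid_low_ratio)
    rts = random_rt(config.n_lipid_low_ratio)
    for i in range(config.n_lipid_low_ratio):
        base = baseline()
        prof = np.full(len(samples), base)
        prof[is_blank | is_qc_blank] = base * 0.5  # blank:control ratio ~2 (< 10)
        add_feature("lipidomics", "blank_contaminant", prof, mzs[i], rts[i])

    intensities = pd.DataFrame(
        np.vstack(intensity_rows),
        index=[r[0] for r in feature_rows],
        columns=samples.index,
    )
    features = pd.DataFrame(
        {
            "mz": [r[1] for r in feature_rows],
            "rt_seconds": [r[2] for r in feature_rows],
            "assay": [r[3] for r in feature_rows],
        },
        index=pd.Index([r[0] for r in feature_rows], name="feature_id"),
    )
    truth = pd.DataFrame(
        {
            "label": [r[4] for r in feature_rows],
            "shape": [r[5] for r in feature_rows],
            "effect_size": [r[6] for r in feature_rows],
            "parent_id": [r[7] for r in feature_rows],
            "rule": [r[8] for r in feature_rows],
            "adduct": [r[9] for r in feature_rows],
            "drift_slope": [r[10] for r in feature_rows],
        },
        index=features.index.copy(),
    )
    table = FeatureTable(intensities, features, samples)
    return table, SimTruth(truth)


# ---------------------------------------------------------------------------
# MS2 simulation and synthetic reference library


def simulate_ms2(
    template: list[tuple[float, float]],
    noise_cv: float = 0.0,
    dropout_p: float = 0.0,
    seed: int = 0,
    precursor_mz: float | None = None,
    name: str = "",
) -> MS2Spectrum:
    """Perturb a fragment template: lognormal intensity noise plus random
    fragment dropout; the surviving base peak is renormalized to 100."""
    if not template:
        raise ValueError("fragment template must be nonempty")
    if not 0 <= dropout_p < 1:
        raise ValueError("dropout_p must be in [0, 1)")
    rng = np.random.default_rng(seed)
    keep = rng.random(len(template)) >= dropout_p
    sigma = math.sqrt(math.log(1 + noise_cv**2)) if noise_cv > 0 else 0.0
    peaks = []
    for (mz, inten), k in zip(template, keep):
        if not k:
            continue
        factor = rng.lognormal(-0.5 * sigma**2, sigma) if sigma > 0 else 1.0
        peaks.append((mz, inten * factor))
    if precursor_mz is None:
        precursor_mz = max(mz for mz, _ in template)
    if peaks:
        top = max(i for _, i in peaks)
        peaks = [(mz, 100.0 * i / top) for mz, i in peaks]
    return MS2Spectrum(precursor_mz, peaks, source="simulated", name=name)


def synthetic_standard_templates(parent_formula: str = chem.CBZ_FORMULA) -> dict:
    """Synthetic stand-in MS2 templates for the demo standards.

    These are NOT measured spectra: fragments are placed at the precursor minus
    common neutral losses, purely so that annotation logic (similarity scoring,
    confidence levels) can be exercised end to end.
    """
    parent = chem.parse_formula(parent_formula)
    m_parent = chem.DEFAULT_ADDUCTS[0].mz(chem.monoisotopic_mass(parent))
    losses = {  # neutral loss name -> (mass, relative intensity of resulting fragment)
        "none": (0.0, 60.0),
        "CHNO": (43.00581, 100.0),
        "CH3NO": (45.02146, 40.0),
        "H2O": (18.010565, 25.0),
    }

    def template_for(mz0: float, loss_names: list[str]) -> list[tuple[float, float]]:
        return [(mz0 - losses[n][0], losses[n][1]) for n in loss_names]

    ep = chem.TransformationRule("epoxidation", add="O").apply(parent)
    m_ep = chem.DEFAULT_ADDUCTS[0].mz(chem.monoisotopic_mass(ep))
    imi = chem.TransformationRule("carbamoyl_loss", remove="CHNO").apply(parent)
    m_imi = chem.DEFAULT_ADDUCTS[0].mz(chem.monoisotopic_mass(imi))
    return {
        "CBZ": (m_parent, template_for(m_parent, ["none", "CHNO", "CH3NO"])),
        "CBZ-Ep": (m_ep, template_for(m_ep, ["none", "CHNO", "H2O"])),
        "iminostilbene": (m_imi, template_for(m_imi, ["none", "H2O"])),
    }


def reference_spectrum_library(seed: int = 0) -> list[MS2Spectrum]:
    """Authentic-standard stand-ins (synthetic) for the local MGF library."""
    out = []
    for name, (prec, template) in synthetic_standard_templates().items():
        sp = simulate_ms2(template, noise_cv=0.0, dropout_p=0.0, seed=seed,
                          precursor_mz=prec, name=name)
        sp.source = "standard"
        out.append(sp)
    return out


def simulate_query_spectra(truth: SimTruth, table: FeatureTable, seed: int = 0) -> dict:
    """MS2 spectra for a subset of bioTP-matched features.

    Mirrors the study narrative: of the mass-matched features, only some
    triggered MS2; among those, the epoxide and the carbamoyl-loss product
    match their standards while the rest yield unrelated spectra.
    """
    rng = np.random.default_rng(seed)
    templates = synthetic_standard_templates()
    out: dict[str, MS2Spectrum] = {}
    biotp = truth.labels[truth.labels["label"] == "biotp"]
    with_ms2 = []
    for fid, row in biotp.iterrows():
        if row["rule"] == "epoxidation" and row["adduct"] == "[M+H]":
            prec, tmpl = templates["CBZ-Ep"]
            out[fid] = simulate_ms2(tmpl, 0.05, 0.0, int(rng.integers(2**31)), prec, fid)
            with_ms2.append(fid)
        elif row["rule"] == "carbamoyl_loss" and row["adduct"] == "[M+H]":
            prec, tmpl = templates["iminostilbene"]
            out[fid] = simulate_ms2(tmpl, 0.05, 0.0, int(rng.integers(2**31)), prec, fid)
            with_ms2.append(fid)
    # three more features with MS2 unrelated to any standard
    others = [f for f in biotp.index if f not in with_ms2][:3]
    for fid in others:
        mz0 = float(table.features.loc[fid, "mz"])
        tmpl = [(mz0 - d, 100.0 / (k + 1)) for k, d in enumerate((1.5, 27.3, 55.9, 71.2))]
        out[fid] = simulate_ms2(tmpl, 0.05, 0.0, int(rng.integers(2**31)), mz0, fid)
    return out
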