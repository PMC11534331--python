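"""Synthetic cohorts and DP-pCASL image data with the study's structure.

The study preset reproduces the published cohort exactly in its discrete
structure (186 subjects: 89 M / 97 F; race 65 White / 27 Latinx / 47 African
American / 47 Asian; age groups 8-35 / 36-61 / 62-92 of sizes 56 / 55 / 75
with per-group sex allocation 31/25, 28/27, 30/45) and calibrates
continuous piecewise-linear mean trajectories of whole-brain kw, CBF and ATT
(knees at 62, 22 and 36 years) so that the expected bin-by-sex means equal
the printed whole-brain group means exactly; residual SDs are chosen so the
total bin SDs match the printed ones.  Ages are integer years, uniform over
each group's range, so the calibration uses the same discrete distribution
the generator samples from.

All generators are pure functions of (preset, seed).
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd
import yaml
from scipy import ndimage

from . import kinetics
from .kinetics import PhysioState
from .protocol import AcquisitionProtocol
from .quantify import AslSeries
from .roi import DEFAULT_AGE_EDGES

__all__ = [
    "FeatureCurve",
    "StudyPreset",
    "study_preset",
    "gm_kw_preset",
    "trajectory_mean",
    "generate_cohort",
    "generate_parameter_maps",
    "generate_dp_pcasl_signals",
    "PRINTED_GROUP_STATS",
]

SEXES = ("M", "F")
BINS = tuple(zip(DEFAULT_AGE_EDGES[:-1], DEFAULT_AGE_EDGES[1:]))  # half-open

#: published whole-brain group mean +/- SD per feature, sex and age group
PRINTED_GROUP_STATS = {
    "kw": {
        "M": ((120.7, 17.4), (117.5, 26.5), (97.9, 31.4)),
        "F": ((121.7, 18.2), (118.9, 14.0), (114.8, 23.7)),
    },
    "cbf": {
        "M": ((51.5, 11.9), (43.9, 10.7), (31.9, 8.5)),
        "F": ((60.5, 10.7), (51.2, 11.7), (39.6, 10.3)),
    },
    "att": {
        "M": ((1325.8, 157.7), (1383.9, 199.6), (1526.7, 117.4)),
        "F": ((1220.2, 134.2), (1334.4, 155.4), (1468.1, 166.9)),
    },
}

KNEES = {"kw": 62.0, "cbf": 22.0, "att": 36.0}

#: per age group: (n male, n female); marginals 89 M / 97 F, bins 56/55/75
SEX_ALLOCATION = ((31, 25), (28, 27), (30, 45))

RACE_COUNTS = {"White": 65, "Latinx": 27, "AfricanAmerican": 47, "Asian": 47}


def _bin_ages(bin_idx: int) -> np.ndarray:
    lo, hi = BINS[bin_idx]
    return np.arange(lo, hi)  # integer ages, upper edge exclusive


@dataclasses.dataclass(frozen=True)
class FeatureCurve:
    """Continuous piecewise-linear mean trajectory with one knee.

    mean(age) = level + pre_slope * min(age - knee, 0)
                      + post_slope * max(age - knee, 0)
    with sex-specific parameters and per-(sex, bin) residual SDs.
    """

    knee: float
    level: dict
    pre_slope: dict
    post_slope: dict
    sigma: dict  # sigma[sex][bin_idx]

    def mean(self, age, sex: str):
        a = np.asarray(age, dtype=float)
        out = (
            self.level[sex]
            + self.pre_slope[sex] * np.minimum(a - self.knee, 0.0)
            + self.post_slope[sex] * np.maximum(a - self.knee, 0.0)
        )
        return out if out.ndim else float(out)


def _calibrate_curve(feature: str) -> FeatureCurve:
    """Solve the 3x3 linear system making bin means equal the printed means."""
    knee = KNEES[feature]
    level, pre, post, sigma = {}, {}, {}, {}
    for sex in SEXES:
        rows, targets = [], []
        for bi in range(3):
            ages = _bin_ages(bi)
            rows.append(
                [
                    1.0,
                    float(np.minimum(ages - knee, 0.0).mean()),
                    float(np.maximum(ages - knee, 0.0).mean()),
                ]
            )
            targets.append(PRINTED_GROUP_STATS[feature][sex][bi][0])
        v, s_pre, s_post = np.linalg.solve(np.array(rows), np.array(targets))
        level[sex], pre[sex], post[sex] = float(v), float(s_pre), float(s_post)
        sig = []
        for bi in range(3):
            ages = _bin_ages(bi)
            m = (
                v
                + s_pre * np.minimum(ages - knee, 0.0)
                + s_post * np.maximum(ages - knee, 0.0)
            )
            target_sd = PRINTED_GROUP_STATS[feature][sex][bi][1]
            resid_var = target_sd**2 - m.var()
            sig.append(float(np.sqrt(max(resid_var, (0.1 * target_sd) ** 2))))
        sigma[sex] = tuple(sig)
    return FeatureCurve(knee=knee, level=level, pre_slope=pre, post_slope=post, sigma=sigma)


@dataclasses.dataclass(frozen=True)
class StudyPreset:
    """Demographics plus per-feature trajectory parameters."""

    name: str
    version: str
    sex_allocation: tuple  # per bin (n_male, n_female)
    race_counts: dict
    curves: dict  # column name -> FeatureCurve
    icv_mean: dict = dataclasses.field(
        default_factory=lambda: {"M": 1500.0, "F": 1330.0}
    )
    icv_sd: float = 110.0
    gm_density_mean: float = 0.55
    gm_density_sd: float = 0.05

    def __post_init__(self) -> None:
        n_m = sum(a[0] for a in self.sex_allocation)
        n_f = sum(a[1] for a in self.sex_allocation)
        if sum(self.race_counts.values()) != n_m + n_f:
            raise ValueError("race counts do not sum to the cohort size")

    @property
    def n_total(self) -> int:
        return sum(a + b for a, b in self.sex_allocation)

    def to_yaml(self) -> str:
        d = dataclasses.asdict(self)
        d["curves"] = {
            k: dataclasses.asdict(c) if dataclasses.is_dataclass(c) else c
            for k, c in self.curves.items()
        }
        return yaml.safe_dump(d, sort_keys=False)

    @classmethod
    def from_yaml(cls, text: str) -> "StudyPreset":
        d = yaml.safe_load(text)
        d["curves"] = {k: FeatureCurve(**c) for k, c in d["curves"].items()}
        d["sex_allocation"] = tuple(tuple(p) for p in d["sex_allocation"])
        return cls(**d)


def study_preset() -> StudyPreset:
    """The default study preset: whole-brain curves calibrated to the printed
    group statistics, plus the gray-matter kw curve (flat to 62, then
    -0.82 min^-1 per year for both sexes)."""
    curves = {f"{feat}_wb": _calibrate_curve(feat) for feat in ("kw", "cbf", "att")}
    curves["kw_gm"] = _gm_kw_curve()
    return StudyPreset(
        name="study",
        version="1.0",
        sex_allocation=SEX_ALLOCATION,
        race_counts=dict(RACE_COUNTS),
        curves=curves,
    )


def _gm_kw_curve() -> FeatureCurve:
    # flat level near the whole-brain young mean; published post-knee slope;
    # residual SD near the printed young-bin whole-brain SDs
    level = {"M": 121.2, "F": 121.2}
    return FeatureCurve(
        knee=62.0,
        level=level,
        pre_slope={"M": 0.0, "F": 0.0},
        post_slope={"M": -0.82, "F": -0.82},
        sigma={"M": (17.0, 17.0, 17.0), "F": (17.0, 17.0, 17.0)},
    )


def gm_kw_preset() -> StudyPreset:
    """Alias of the study preset; the GM kw column is ``kw_gm``."""
    return study_preset()


def trajectory_mean(age, sex: str, feature: str, preset: StudyPreset):
    """Expected feature value at (age, sex) under the preset's curve."""
    return preset.curves[feature].mean(age, sex)


def _bin_index(age: float) -> int:
    for i, (lo, hi) in enumerate(BINS):
        if lo <= age < hi:
            return i
    raise ValueError(f"age {age} outside the study range")


def generate_cohort(
    preset: StudyPreset, seed: int, n_scale: int = 1
) -> pd.DataFrame:
    """Draw a cohort table with exact preset counts and calibrated features.

    Ages are integer years uniform within each group; sex, race and group
    sizes hit the preset counts exactly.  For every feature column a
    matching ``<column>_true`` column stores the generating trajectory mean.
    Byte-identical for equal seeds.
    """
    rng = np.random.default_rng(seed)
    ages, sexes, bins = [], [], []
    for bi, (n_m, n_f) in enumerate(preset.sex_allocation):
        lo, hi = BINS[bi]
        for sex, n in (("M", n_m * n_scale), ("F", n_f * n_scale)):
            ages.append(rng.integers(lo, hi, size=n))
            sexes += [sex] * n
            bins += [bi] * n
    age = np.concatenate(ages)
    sex = np.array(sexes)
    bin_idx = np.array(bins)
    n = len(age)

    race = np.repeat(
        list(preset.race_counts.keys()),
        [c * n_scale for c in preset.race_counts.values()],
    )
    rng.shuffle(race)

    icv = np.where(
        sex == "M",
        rng.normal(preset.icv_mean["M"], preset.icv_sd, n),
        rng.normal(preset.icv_mean["F"], preset.icv_sd, n),
    )
    gm_density = np.clip(
        rng.normal(preset.gm_density_mean, preset.gm_density_sd, n), 0.3, 0.8
    )

    df = pd.DataFrame(
        {
            "subject_id": [f"S{i:04d}" for i in range(n)],
            "age": age,
            "sex": sex,
            "race": race,
            "icv": icv,
            "gm_density": gm_density,
        }
    )
    for col, curve in preset.curves.items():
        truth = np.array([curve.mean(a, s) for a, s in zip(age, sex)])
        noise_sd = np.array([curve.sigma[s][b] for s, b in zip(sex, bin_idx)])
        df[col] = truth + rng.normal(0.0, 1.0, n) * noise_sd
        df[f"{col}_true"] = truth
    df.attrs["units"] = {
        "kw": "min^-1",
        "cbf": "ml/100g/min",
        "att": "ms",
        "icv": "ml",
    }
    df.attrs["preset"] = preset.name
    return df


@dataclasses.dataclass
class ParameterFields:
    """Per-subject 3-D truth fields over a toy two-region atlas."""

    cbf: np.ndarray
    att: np.ndarray
    kw: np.ndarray
    atlas: np.ndarray
    mask: np.ndarray


def generate_parameter_maps(
    truth_by_label: dict[int, tuple[float, float, float]],
    shape=(16, 16, 16),
    smoothness: float = 0.0,
    noise_frac: float = 0.0,
    seed: int = 0,
) -> ParameterFields:
    """Smooth random fields centered on per-region (cbf, att, kw) truths.

    ``truth_by_label`` maps atlas labels to parameter triplets; the toy
    atlas splits the grid into contiguous slabs along the first axis, one
    per label.  ``noise_frac`` scales zero-mean Gaussian perturbations
    relative to each region's truth value; ``smoothness`` (voxels, Gaussian
    sigma) spatially correlates them (0 means i.i.d.).  Region means equal
    the truths exactly when ``noise_frac`` is 0.
    """
    labels = sorted(truth_by_label)
    atlas = np.zeros(shape, dtype=int)
    edges = np.linspace(0, shape[0], len(labels) + 1).astype(int)
    for lab, (a, b) in zip(labels, zip(edges[:-1], edges[1:])):
        atlas[a:b] = lab
    rng = np.random.default_rng(seed)
    fields = {}
    for fi, name in enumerate(("cbf", "att", "kw")):
        base = np.zeros(shape)
        for lab in labels:
            base[atlas == lab] = truth_by_label[lab][fi]
        if noise_frac > 0:
            noise = rng.standard_normal(shape)
            if smoothness > 0:
                noise = ndimage.gaussian_filter(noise, smoothness)
                sd = noise.std()
                if sd > 0:
                    noise = noise / sd
            scale = np.zeros(shape)
            for lab in labels:
                scale[atlas == lab] = abs(truth_by_label[lab][fi]) * noise_frac
            base = base + noise * scale
        fields[name] = base
    return ParameterFields(
        cbf=np.clip(fields["cbf"], 0.0, None),
        att=fields["att"],
        kw=np.clip(fields["kw"], 0.0, None),
        atlas=atlas,
        mask=np.ones(shape, dtype=bool),
    )


def generate_dp_pcasl_signals(
    fields: ParameterFields,
    proto: AcquisitionProtocol | None = None,
    noise_sd: float = 0.0,
    seed: int = 0,
    m0_value: float = 1000.0,
    n_pairs: tuple[int, int] = (15, 20),
) -> AslSeries:
    """Forward-model a DP-pCASL control/label series from parameter fields.

    Per protocol condition the noise-free difference fraction is computed
    with the package's own kinetic models (short-PLD pair: arrival-reference
    and transit-time signals for FEAST; long-PLD pair: two-compartment total
    and tissue-only signals), replicated to the acquisition's repeat counts
    (15 pairs at the short PLD, 20 at the long), and embedded into control
    and label volumes around a uniform M0.  ``noise_sd`` is the SD of a
    single-pair difference relative to the condition's mean difference
    amplitude; doubling it doubles the repeat-wise difference SD.
    """
    proto = proto or AcquisitionProtocol()
    rng = np.random.default_rng(seed)
    pld_short, pld_long = min(proto.plds), max(proto.plds)
    b_short = proto.b_values_per_pld[proto.plds.index(pld_short)]
    b_long = proto.b_values_per_pld[proto.plds.index(pld_long)]
    floor_ms = proto.att_floor * kinetics.MS

    state = PhysioState(cbf=fields.cbf, att=fields.att, kw=fields.kw)
    spa = kinetics.spa_forward(state, proto, pld_long)
    dm = {
        (pld_short, b_short[0]): kinetics.buxton_forward(
            PhysioState(cbf=fields.cbf, att=floor_ms), proto, pld_short
        ),
        (pld_short, b_short[1]): kinetics.buxton_forward(
            PhysioState(cbf=fields.cbf, att=fields.att), proto, pld_short
        ),
        (pld_long, b_long[0]): np.asarray(spa.dM_total),
        (pld_long, b_long[1]): np.asarray(spa.dM_tis),
    }
    counts = {pld_short: n_pairs[0], pld_long: n_pairs[1]}
    m0 = np.full(fields.mask.shape, m0_value)
    data = {}
    for cond, frac in dm.items():
        pairs = counts[cond[0]]
        amp = float(np.abs(frac[fields.mask]).mean())
        sigma_vol = noise_sd * amp * m0_value / np.sqrt(2.0)
        vols = np.empty(fields.mask.shape + (2 * pairs,))
        for j in range(pairs):
            eps_c = rng.normal(0.0, sigma_vol, m0.shape) if sigma_vol > 0 else 0.0
            eps_l = rng.normal(0.0, sigma_vol, m0.shape) if sigma_vol > 0 else 0.0
            vols[..., 2 * j] = m0 + eps_c
            vols[..., 2 * j + 1] = m0 * (1.0 - frac) + eps_l
        data[cond] = vols
    return AslSeries(data=data, m0=m0, mask=fields.mask, order="control-first")
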