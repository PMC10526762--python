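"""Synthetic phantoms and copula-coupled survival data with known truth.

The real study cohort (radiation-planning T1C MRI of 70 glioma subjects,
13 with rapid early progression) is not publicly available, so every
downstream stage of the pipeline is exercised on phantoms generated here:

* fractional-Brownian-motion (fBm) textured volumes with a controllable
  Hurst exponent, synthesized spectrally so the roughness is exact;
* nested ellipsoidal tumor phantoms following the BraTS label convention
  (1 = necrosis, 2 = edema, 4 = enhancing tumor);
* survival/censoring time pairs whose dependence is a Clayton copula with
  Cox-type covariate effects on Weibull margins, sampled by closed-form
  conditional inversion;
* feature tables shaped like the study cohort (13 REP / 57 non-REP, 600
  features) with a configurable number of informative columns.

All generators are deterministic given their seed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .copula import ClaytonCopula

__all__ = [
    "FbmField",
    "PhantomStudy",
    "CopulaSurvivalTruth",
    "SurvivalData",
    "gen_fbm_volume",
    "gen_phantom_study",
    "gen_copula_survival",
    "gen_rep_feature_table",
]


# ----------------------------------------------------------------------
# fractional Brownian fields
# ----------------------------------------------------------------------

@dataclass(frozen=True)
class FbmField:
    """A spectrally synthesized fBm-like field.

    ``values`` is zero-mean, unit-variance before any affine rescaling by
    the caller; ``hurst`` is the target Hölder/Hurst exponent in (0, 1).
    """

    values: np.ndarray
    hurst: float
    seed: int


def gen_fbm_volume(size: int, hurst: float, seed: int, ndim: int = 3,
                   alias_order: int = 1) -> FbmField:
    """Synthesize an isotropic fBm field by Fourier spectral synthesis.

    The target power spectrum is ``(sum_k f_k^2)^-((2H+d)/2)`` in ``d``
    dimensions, i.e. amplitude ~ f^-((2H+d)/2), which yields increments
    with variance ~ h^(2H). Sampling a continuous fBm on a lattice folds
    all above-Nyquist power back into the band, so the synthesized power
    is the alias sum over integer frequency shifts up to ``alias_order``
    plus the analytic isotropic integral of the remaining tail; without
    this the lag-1 increments come out too smooth and small-lag Hurst
    estimates are biased upward.

    Parameters
    ----------
    size : voxels per axis (>= 16 so fractal scaling has room).
    hurst : target exponent, strictly inside (0, 1).
    seed : RNG seed; the output is bit-reproducible.
    ndim : 2 or 3.
    """
    if size < 16:
        raise ValueError(f"size {size} too small to carry fractal scaling (need >= 16)")
    if not (0.0 < hurst < 1.0):
        raise ValueError(f"hurst must be in (0, 1), got {hurst}")
    if ndim not in (2, 3):
        raise ValueError("ndim must be 2 or 3")

    import itertools

    rng = np.random.default_rng(seed)
    shape = (size,) * ndim
    freqs = np.meshgrid(*(np.fft.fftfreq(size) for _ in range(ndim)), indexing="ij")
    expo = -(2.0 * hurst + ndim) / 2.0
    power = np.zeros(shape)
    for shift in itertools.product(range(-alias_order, alias_order + 1), repeat=ndim):
        f2 = sum((f + s) ** 2 for f, s in zip(freqs, shift))
        with np.errstate(divide="ignore"):
            power += np.where(f2 > 0, f2 ** expo, 0.0)
    # tail of the alias sum beyond the box, as an isotropic white floor
    sphere_surface = 2.0 * np.pi if ndim == 2 else 4.0 * np.pi
    power += sphere_surface * (alias_order + 0.5) ** (-2.0 * hurst) / (2.0 * hurst)
    amp = np.sqrt(power)
    amp.flat[0] = 0.0  # zero mean

    noise = rng.standard_normal(shape) + 1j * rng.standard_normal(shape)
    fld = np.fft.ifftn(amp * noise).real
    fld -= fld.mean()
    sd = fld.std()
    if sd > 0:
        fld /= sd
    return FbmField(values=fld, hurst=hurst, seed=seed)


# ----------------------------------------------------------------------
# tumor phantoms
# ----------------------------------------------------------------------

@dataclass
class PhantomStudy:
    """One phantom subject: intensity volume, BraTS-coded labels, truth."""

    intensity: np.ndarray
    labels: np.ndarray
    spacing: tuple[float, float, float]
    truth: dict

    def brain_mask(self) -> np.ndarray:
        return np.asarray(self.truth["brain_mask"], dtype=bool)


# BraTS label codes
NECROSIS, EDEMA, ENHANCING = 1, 2, 4

_DEFAULT_SEMI_AXES = {
    "edema": (22.0, 19.0, 17.0),
    "enhancing": (14.0, 12.0, 10.0),
    "necrosis": (8.0, 6.5, 5.0),
}
_DEFAULT_MEANS = {"background": 20.0, "edema": 60.0, "enhancing": 100.0, "necrosis": 35.0}
_DEFAULT_HURST = {"edema": 0.6, "enhancing": 0.4, "necrosis": 0.5}


def _ellipsoid_mask(shape, center, semi_axes, spacing, rotation=None):
    grids = np.meshgrid(*(np.arange(s) for s in shape), indexing="ij")
    coords = np.stack([(g - c) * sp for g, c, sp in zip(grids, center, spacing)])
    if rotation is not None:
        flat = coords.reshape(3, -1)
        coords = (np.asarray(rotation) @ flat).reshape(coords.shape)
    q = sum((coords[i] / semi_axes[i]) ** 2 for i in range(3))
    return q <= 1.0


def gen_phantom_study(
    semi_axes: dict | None = None,
    region_means: dict | None = None,
    region_hurst: dict | None = None,
    noise_sd: float = 2.0,
    texture_sd: float = 8.0,
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0),
    seed: int = 0,
    size: int = 64,
    rotation: np.ndarray | None = None,
    brain_semi_axes: tuple[float, float, float] | None = None,
) -> PhantomStudy:
    """Generate a nested ellipsoidal tumor phantom.

    Labels are nested necrosis < enhancing < edema (BraTS codes {1, 2, 4});
    intensity is region mean + scaled fBm texture + Gaussian noise.
    ``semi_axes`` must strictly decrease from edema to enhancing to
    necrosis along every axis, otherwise the phantom is refused.
    """
    semi_axes = dict(_DEFAULT_SEMI_AXES if semi_axes is None else semi_axes)
    region_means = dict(_DEFAULT_MEANS if region_means is None else region_means)
    for k in ("edema", "enhancing", "necrosis"):
        if k not in semi_axes:
            raise ValueError(f"semi_axes missing region {k!r}")
    ed, en, nec = (np.asarray(semi_axes[k], float) for k in ("edema", "enhancing", "necrosis"))
    if not (np.all(ed > en) and np.all(en > nec)):
        raise ValueError("semi-axes must strictly decrease edema > enhancing > necrosis on every axis")
    if np.any(nec <= 0):
        raise ValueError("semi-axes must be positive")

    rng = np.random.default_rng(seed)
    shape = (size,) * 3
    center = tuple((s - 1) / 2.0 for s in shape)
    masks = {
        "edema": _ellipsoid_mask(shape, center, ed, spacing, rotation),
        "enhancing": _ellipsoid_mask(shape, center, en, spacing, rotation),
        "necrosis": _ellipsoid_mask(shape, center, nec, spacing, rotation),
    }
    labels = np.zeros(shape, dtype=np.int16)
    labels[masks["edema"]] = EDEMA
    labels[masks["enhancing"]] = ENHANCING
    labels[masks["necrosis"]] = NECROSIS

    if brain_semi_axes is None:
        brain_semi_axes = tuple(min(float(a) * 1.25, (size / 2 - 1) * min(spacing)) for a in ed)
        brain_semi_axes = tuple(max(b, e + 2.0) for b, e in zip(brain_semi_axes, ed))
    brain = _ellipsoid_mask(shape, center, np.asarray(brain_semi_axes, float), spacing, rotation)
    brain |= labels > 0

    intensity = np.full(shape, region_means.get("background", 0.0), dtype=float)
    label_of = {"necrosis": NECROSIS, "edema": EDEMA, "enhancing": ENHANCING}
    for i, region in enumerate(("edema", "enhancing", "necrosis")):
        reg_mask = labels == label_of[region]
        intensity[reg_mask] = region_means[region]
        if region_hurst is not None and region in region_hurst and texture_sd > 0:
            tex = gen_fbm_volume(size, region_hurst[region], seed + 101 + i).values
            intensity[reg_mask] += texture_sd * tex[reg_mask]
    if noise_sd > 0:
        intensity += noise_sd * rng.standard_normal(shape)

    truth = {
        "region_means": region_means,
        "region_hurst": dict(region_hurst) if region_hurst else {},
        "semi_axes": {k: tuple(map(float, np.asarray(v))) for k, v in semi_axes.items()},
        "rotation": None if rotation is None else np.asarray(rotation).tolist(),
        "brain_semi_axes": tuple(map(float, brain_semi_axes)),
        "brain_mask": brain,
        "noise_sd": noise_sd,
        "texture_sd": texture_sd,
        "seed": seed,
    }
    return PhantomStudy(intensity=intensity, labels=labels, spacing=tuple(spacing), truth=truth)


# ----------------------------------------------------------------------
# copula-coupled survival data
# ----------------------------------------------------------------------

@dataclass(frozen=True)
class CopulaSurvivalTruth:
    """Ground truth for a dependent-censoring survival simulation.

    ``beta``/``gamma`` are log-hazard effects on the death time T and the
    censoring time U; ``alpha`` is the Clayton dependence (Kendall tau =
    alpha/(alpha+2)); baselines are Weibull (shape, scale-days) pairs.
    Defaults mimic a 70-subject glioma cohort with median survival around
    a year and roughly a third of subjects censored.
    """

    beta: tuple = (0.7,)
    gamma: tuple = (0.3,)
    alpha: float = 2.0
    baseline_death: tuple[float, float] = (1.3, 600.0)
    baseline_censor: tuple[float, float] = (1.2, 1100.0)
    n: int = 70
    seed: int = 0

    def __post_init__(self):
        if self.alpha < 0:
            raise ValueError("alpha must be >= 0")
        for shape, scale in (self.baseline_death, self.baseline_censor):
            if shape <= 0 or scale <= 0:
                raise ValueError("Weibull shapes and scales must be > 0")
        if self.n < 20:
            raise ValueError("n must be >= 20")

    @property
    def kendall_tau(self) -> float:
        return self.alpha / (self.alpha + 2.0)


@dataclass
class SurvivalData:
    """Observed survival records: Y = min(T, U), delta = 1(T <= U).

    ``truth`` (simulation only) retains the latent T and U so dependence
    diagnostics can be tested; real data never carry it.
    """

    time: np.ndarray
    event: np.ndarray
    x: pd.DataFrame
    ids: list = field(default_factory=list)
    truth: pd.DataFrame | None = None

    def __post_init__(self):
        self.time = np.asarray(self.time, dtype=float)
        self.event = np.asarray(self.event, dtype=int)
        if np.any(self.time <= 0):
            raise ValueError("observed times must be > 0")
        if not set(np.unique(self.event)) <= {0, 1}:
            raise ValueError("event indicator must be binary")
        if len(self.x) != len(self.time):
            raise ValueError("covariate rows must match number of subjects")
        if not self.ids:
            self.ids = [f"S{i:04d}" for i in range(len(self.time))]

    @property
    def n(self) -> int:
        return len(self.time)

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame({"subject_id": self.ids, "time_days": self.time, "event": self.event})
        df = pd.concat([df, self.x.reset_index(drop=True)], axis=1)
        if self.truth is not None:
            t = self.truth.reset_index(drop=True).add_prefix("truth_")
            df = pd.concat([df, t], axis=1)
        return df

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "SurvivalData":
        covs = [c for c in df.columns
                if c not in ("subject_id", "time_days", "event") and not c.startswith("truth_")]
        truth_cols = [c for c in df.columns if c.startswith("truth_")]
        truth = df[truth_cols].rename(columns=lambda c: c[len("truth_"):]) if truth_cols else None
        return cls(
            time=df["time_days"].to_numpy(),
            event=df["event"].to_numpy(),
            x=df[covs].copy(),
            ids=list(df["subject_id"]) if "subject_id" in df else [],
            truth=truth,
        )


def _weibull_inverse_survival(v, shape, scale, linpred):
    """Solve S(t | x) = v for a Cox model with Weibull baseline."""
    # S(t|x) = exp(-(t/scale)^shape * e^linpred)
    return scale * (-np.log(v) * np.exp(-linpred)) ** (1.0 / shape)


def gen_copula_survival(
    truth: CopulaSurvivalTruth,
    covariates: np.ndarray | pd.DataFrame | None = None,
) -> SurvivalData:
    """Simulate (Y, delta, x) with Clayton-dependent death and censoring.

    The pair of survival probabilities (V_T, V_U) is drawn from the Clayton
    copula by conditional inversion and pushed through subject-specific
    Cox-Weibull marginals; the observed record is Y = min(T, U) with
    delta = 1(T <= U). Deterministic given ``truth.seed``.
    """
    rng = np.random.default_rng(truth.seed)
    beta = np.asarray(truth.beta, float)
    gamma = np.asarray(truth.gamma, float)
    n = truth.n
    if covariates is None:
        x = rng.standard_normal((n, len(beta)))
        xdf = pd.DataFrame(x, columns=[f"x{j}" for j in range(len(beta))])
    else:
        xdf = pd.DataFrame(covariates).reset_index(drop=True)
        if len(xdf) != n:
            raise ValueError(f"covariates must have n={n} rows, got {len(xdf)}")
        x = xdf.to_numpy(dtype=float)
    if x.shape[1] != len(beta) or x.shape[1] != len(gamma):
        raise ValueError("beta/gamma length must match covariate count")

    cop = ClaytonCopula(truth.alpha)
    v_t, v_u = cop.sample(n, rng)
    lp_t = x @ beta
    lp_u = x @ gamma
    t = _weibull_inverse_survival(v_t, *truth.baseline_death, lp_t)
    u = _weibull_inverse_survival(v_u, *truth.baseline_censor, lp_u)
    y = np.minimum(t, u)
    delta = (t <= u).astype(int)
    y = np.maximum(y, 1e-8)
    return SurvivalData(
        time=y, event=delta, x=xdf,
        truth=pd.DataFrame({"T": t, "U": u, "alpha": truth.alpha}),
    )


# ----------------------------------------------------------------------
# REP-shaped feature tables
# ----------------------------------------------------------------------

def gen_rep_feature_table(
    n_pos: int = 13,
    n_neg: int = 57,
    n_features: int = 600,
    n_informative: int = 3,
    effect: float = 2.0,
    seed: int = 0,
    label_name: str = "rep",
) -> pd.DataFrame:
    """A cohort-shaped feature table with a known informative subset.

    The first ``n_informative`` features are shifted upward by ``effect``
    (in SD units) in the positive class; everything else is standard
    normal noise. Defaults mirror a 13 REP / 57 non-REP cohort with 600
    extracted features.
    """
    if n_informative > n_features:
        raise ValueError("n_informative must be <= n_features")
    if n_pos < 5 or n_neg < 5:
        raise ValueError("need at least 5 subjects per class")
    rng = np.random.default_rng(seed)
    n = n_pos + n_neg
    x = rng.standard_normal((n, n_features))
    labels = np.r_[np.ones(n_pos, int), np.zeros(n_neg, int)]
    x[:n_pos, :n_informative] += effect
    cols = [f"feature_{j:04d}" for j in range(n_features)]
    df = pd.DataFrame(x, columns=cols, index=[f"S{i:04d}" for i in range(n)])
    df[label_name] = labels
    return df


# ----------------------------------------------------------------------
# on-disk phantom cohorts
# ----------------------------------------------------------------------

def write_phantom(study: PhantomStudy, out_dir: str | Path, subject_id: str) -> dict:
    """Write a phantom as paired NIfTI files plus a JSON truth sidecar."""
    import nibabel as nib

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    affine = np.diag(list(study.spacing) + [1.0])
    img_path = out_dir / f"{subject_id}_T1C.nii.gz"
    lab_path = out_dir / f"{subject_id}_labels.nii.gz"
    nib.save(nib.Nifti1Image(study.intensity.astype(np.float32), affine), img_path)
    nib.save(nib.Nifti1Image(study.labels.astype(np.int16), affine), lab_path)
    truth = {k: v for k, v in study.truth.items() if k != "brain_mask"}
    truth_path = out_dir / f"{subject_id}_truth.json"
    truth_path.write_text(json.dumps(truth, indent=1, default=float))
    return {"subject_id": subject_id, "image": str(img_path), "labels": str(lab_path),
            "truth": str(truth_path)}
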