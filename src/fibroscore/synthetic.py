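"""Synthetic study material: CT phantoms and patient cohorts.

Phantoms
--------
A phantom is a rectangular HU grid holding a soft-tissue body (an elliptic
cylinder) containing two ellipsoidal lungs, surrounded by exterior air.
Lung voxels are drawn fibrotic with a configurable design probability,
optionally weighted toward the pleura or the lung bases; normal parenchyma
draws HU from Normal(-850, 40) and fibrotic tissue from Normal(-600, 50),
matching the attenuation ranges the threshold method discriminates.  Only
the HU distribution and its coarse spatial weighting are modelled — that is
what a purely threshold-based score can see — not airway/vessel anatomy or
reconstruction noise texture.

Ground truth is computed post hoc by direct voxel counting on the emitted
volume: the realized fibrotic fraction is the number of geometric-lung
voxels with HU in (-700, -200] divided by those with HU in [-1024, -200],
so scoring the phantom with its own lung mask reproduces it exactly.

Cohorts
-------
Patient records are drawn from a Gaussian copula: a latent multivariate
normal is transformed, per variable, by a monotone map to the requested
marginal (affine + clamping to the scale bounds for continuous variables;
quantile thresholding for binaries).  Because clamping and thresholding
attenuate correlations, each pairwise latent correlation is calibrated
numerically (common-random-number Monte Carlo + root finding) so that the
post-transform Pearson correlation hits its target; the latent matrix is
repaired to the nearest positive-semidefinite correlation matrix when
needed, and the achieved ("effective") pairwise correlations are reported
alongside the samples.
"""

from __future__ import annotations

import dataclasses
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import optimize
from scipy import stats as sps

from .ct_io import CTVolume, VoxelMask
from .cam import HuThresholds, DEFAULT_THRESHOLDS

# ---------------------------------------------------------------------------
# Phantoms
# ---------------------------------------------------------------------------


@dataclasses.dataclass
class Ellipsoid:
    """Axis-aligned ellipsoid: centre and semi-axes in mm (slice, row, col)."""

    centre_mm: tuple[float, float, float]
    radii_mm: tuple[float, float, float]


@dataclasses.dataclass
class PhantomSpec:
    grid_shape: tuple[int, int, int] = (64, 96, 96)
    spacing_mm: tuple[float, float, float] = (1.0, 1.0, 1.0)
    lung_geometry: tuple[Ellipsoid, Ellipsoid] | None = None  # None -> derived
    body_hu: float = 40.0
    air_hu: float = -1000.0
    normal_hu_mean: float = -850.0
    normal_hu_sd: float = 40.0
    fibrotic_hu_mean: float = -600.0
    fibrotic_hu_sd: float = 50.0
    design_fibrotic_fraction: float = 0.0
    pattern: str = "uniform"  # uniform | subpleural | basal
    hu_shift: float = 0.0  # global inspiration-level offset
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.design_fibrotic_fraction <= 1.0:
            raise ValueError("design_fibrotic_fraction must lie in [0, 1]")
        if self.pattern not in ("uniform", "subpleural", "basal"):
            raise ValueError(f"unknown pattern: {self.pattern!r}")

    @property
    def extent_mm(self) -> tuple[float, float, float]:
        return tuple(n * s for n, s in zip(self.grid_shape, self.spacing_mm))

    def resolved_lungs(self) -> tuple[Ellipsoid, Ellipsoid]:
        if self.lung_geometry is not None:
            return self.lung_geometry
        ez, ey, ex = self.extent_mm
        radii = (0.38 * ez, 0.33 * ey, 0.18 * ex)
        return (
            Ellipsoid(centre_mm=(0.5 * ez, 0.5 * ey, 0.28 * ex), radii_mm=radii),
            Ellipsoid(centre_mm=(0.5 * ez, 0.5 * ey, 0.72 * ex), radii_mm=radii),
        )


@dataclasses.dataclass
class PhantomTruth:
    lung_mask: VoxelMask
    fibrotic_voxel_count: int
    lung_voxel_count: int
    realized_fibrotic_fraction: float


def _voxel_centres_mm(spec: PhantomSpec):
    return [
        (np.arange(n) + 0.5) * s
        for n, s in zip(spec.grid_shape, spec.spacing_mm)
    ]


def _ellipsoid_field(spec: PhantomSpec, ell: Ellipsoid) -> np.ndarray:
    """Normalized squared radius: <= 1 inside the ellipsoid."""
    zc, yc, xc = _voxel_centres_mm(spec)
    dz = (zc - ell.centre_mm[0]) / ell.radii_mm[0]
    dy = (yc - ell.centre_mm[1]) / ell.radii_mm[1]
    dx = (xc - ell.centre_mm[2]) / ell.radii_mm[2]
    return (
        dz[:, None, None] ** 2 + dy[None, :, None] ** 2 + dx[None, None, :] ** 2
    )


def _check_geometry(spec: PhantomSpec) -> None:
    extent = spec.extent_mm
    for ell in spec.resolved_lungs():
        for c, r, e in zip(ell.centre_mm, ell.radii_mm, extent):
            if r <= 0 or c - r < 0 or c + r > e:
                raise ValueError("geometry outside grid")


def generate_phantom(spec: PhantomSpec) -> tuple[CTVolume, PhantomTruth]:
    """Build one phantom volume and its voxel-counted ground truth."""
    _check_geometry(spec)
    rng = np.random.default_rng(spec.seed)
    shape = spec.grid_shape
    ez, ey, ex = spec.extent_mm

    # Body: elliptic cylinder spanning all slices.
    zc, yc, xc = _voxel_centres_mm(spec)
    dy = (yc - 0.5 * ey) / (0.47 * ey)
    dx = (xc - 0.5 * ex) / (0.47 * ex)
    body = (dy[:, None] ** 2 + dx[None, :] ** 2) <= 1.0
    body = np.broadcast_to(body, shape)

    lungs = spec.resolved_lungs()
    fields = [_ellipsoid_field(spec, ell) for ell in lungs]
    lung_mask = (fields[0] <= 1.0) | (fields[1] <= 1.0)

    hu = np.full(shape, spec.air_hu, dtype=np.float32)
    hu[body] = spec.body_hu
    n_lung = int(lung_mask.sum())
    if n_lung:
        p = _fibrotic_probability(spec, fields, lung_mask)
        fibrotic = rng.random(n_lung) < p
        draws = np.where(
            fibrotic,
            rng.normal(spec.fibrotic_hu_mean, spec.fibrotic_hu_sd, n_lung),
            rng.normal(spec.normal_hu_mean, spec.normal_hu_sd, n_lung),
        )
        hu[lung_mask] = draws
    hu += spec.hu_shift

    volume = CTVolume(
        voxels=hu,
        spacing_mm=spec.spacing_mm,
        patient_id=f"phantom-{spec.seed}",
        meta={"design_fibrotic_fraction": spec.design_fibrotic_fraction},
    )
    truth = _count_truth(volume, VoxelMask(flags=lung_mask, label="lung_truth"))
    return volume, truth


def _fibrotic_probability(
    spec: PhantomSpec, fields: list[np.ndarray], lung_mask: np.ndarray
) -> np.ndarray:
    """Per-lung-voxel fibrosis probability with mean = design fraction."""
    f = spec.design_fibrotic_fraction
    if spec.pattern == "uniform" or f == 0.0:
        return np.full(int(lung_mask.sum()), f)
    if spec.pattern == "subpleural":
        # rho^2 field: 0 at centre, 1 at pleura; weight rises toward pleura.
        rho2 = np.minimum(fields[0], fields[1])[lung_mask]
        w = 0.25 + rho2
    else:  # basal: weight decreasing from base (slice 0) to apex
        z_idx = np.nonzero(lung_mask)[0].astype(float)
        z_rel = (z_idx - z_idx.min()) / max(z_idx.max() - z_idx.min(), 1.0)
        w = 2.0 - z_rel
    p = f * w / w.mean()
    # Clipping to [0,1] can bias the mean when the design fraction is high;
    # one renormalisation pass keeps the mean on target in practice.
    for _ in range(4):
        p = np.clip(p, 0.0, 1.0)
        if abs(p.mean() - f) < 1e-12 or p.mean() == 0:
            break
        p = p * (f / p.mean())
    return np.clip(p, 0.0, 1.0)


def _count_truth(
    volume: CTVolume,
    lung_mask: VoxelMask,
    thresholds: HuThresholds = DEFAULT_THRESHOLDS,
) -> PhantomTruth:
    hu = volume.voxels[lung_mask.flags]
    in_lung = (hu >= thresholds.lung_low) & (hu <= thresholds.lung_high)
    fibrotic = in_lung & (hu > thresholds.normal_cut)
    n_lung = int(in_lung.sum())
    n_fib = int(fibrotic.sum())
    return PhantomTruth(
        lung_mask=lung_mask,
        fibrotic_voxel_count=n_fib,
        lung_voxel_count=n_lung,
        realized_fibrotic_fraction=(n_fib / n_lung) if n_lung else float("nan"),
    )


# ---------------------------------------------------------------------------
# Cohorts
# ---------------------------------------------------------------------------


@dataclasses.dataclass(frozen=True)
class ContinuousMarginal:
    mean: float
    sd: float
    low: float
    high: float
    integer: bool = False


@dataclasses.dataclass(frozen=True)
class BinaryMarginal:
    p: float  # prevalence of the positive level
    levels: tuple = (False, True)  # (negative, positive)


Marginal = ContinuousMarginal | BinaryMarginal


@dataclasses.dataclass
class CohortSpec:
    n: int
    marginals: Mapping[str, Marginal]
    correlation_targets: Mapping[tuple[str, str], float]
    seed: int = 0

    def __post_init__(self) -> None:
        names = set(self.marginals)
        for (a, b), r in self.correlation_targets.items():
            if a not in names or b not in names:
                raise ValueError(f"correlation target names unknown: ({a}, {b})")
            if a == b or not -1.0 < r < 1.0:
                raise ValueError(f"invalid correlation target ({a}, {b}) = {r}")


@dataclasses.dataclass
class PatientRecord:
    id: str
    age: float
    sex: str
    subtype: str
    disease_duration: float
    mrss: int
    borg: float
    vas_breathing: float
    haq_di: float
    anti_topo_I: bool
    anti_centromere: bool
    dlco_pct: float
    fvc_pct: float
    covr_extent: float
    covr_severity: float
    covr_total: float
    cam_fibrosis_pct: float


#: Bounds of each patient-record scale, used for validation and clamping.
RECORD_BOUNDS: dict[str, tuple[float, float]] = {
    "age": (18.0, 95.0),
    "disease_duration": (0.0, 60.0),
    "mrss": (0.0, 51.0),
    "borg": (0.0, 10.0),
    "vas_breathing": (0.0, 100.0),
    "haq_di": (0.0, 3.0),
    "dlco_pct": (10.0, 150.0),
    "fvc_pct": (10.0, 160.0),
    "covr_total": (0.0, 30.0),
    "cam_fibrosis_pct": (0.0, 100.0),
}

#: Share of the mean CoVR total carried by the extent component.
_EXTENT_SHARE = 6.30 / (6.30 + 6.96)


def default_cohort_spec(n: int = 126, seed: int = 0) -> CohortSpec:
    """Demonstration preset: SSc-ILD-like marginals and the univariate
    correlation structure among the imaging, physiologic and patient-centred
    measures (CaM-CoVR 0.718, CaM-FVC -0.556, CaM-DLco -0.670, CaM-HAQ
    0.597, Borg-VAS 0.627, HAQ-Borg 0.546; remaining pairs 0, repaired to
    the nearest positive-semidefinite matrix).  A demonstration preset, not
    ground truth."""
    b = RECORD_BOUNDS
    marginals: dict[str, Marginal] = {
        "age": ContinuousMarginal(60.68, 10.74, *b["age"]),
        "disease_duration": ContinuousMarginal(11.15, 7.96, *b["disease_duration"]),
        "mrss": ContinuousMarginal(10.22, 7.37, *b["mrss"], integer=True),
        "borg": ContinuousMarginal(2.59, 1.62, *b["borg"]),
        "vas_breathing": ContinuousMarginal(29.24, 17.64, *b["vas_breathing"]),
        "haq_di": ContinuousMarginal(0.84, 0.35, *b["haq_di"]),
        "dlco_pct": ContinuousMarginal(71.59, 14.39, *b["dlco_pct"]),
        "fvc_pct": ContinuousMarginal(80.69, 18.63, *b["fvc_pct"]),
        "covr_total": ContinuousMarginal(13.22, 6.98, *b["covr_total"]),
        "cam_fibrosis_pct": ContinuousMarginal(12.68, 7.99, *b["cam_fibrosis_pct"]),
        "sex": BinaryMarginal(p=0.837, levels=("M", "F")),
        "subtype": BinaryMarginal(p=55 / 126, levels=("lcSSc", "dcSSc")),
        "anti_topo_I": BinaryMarginal(p=0.325),
        "anti_centromere": BinaryMarginal(p=0.436),
    }
    targets = {
        ("cam_fibrosis_pct", "covr_total"): 0.718,
        ("cam_fibrosis_pct", "fvc_pct"): -0.556,
        ("cam_fibrosis_pct", "dlco_pct"): -0.670,
        ("cam_fibrosis_pct", "haq_di"): 0.597,
        ("borg", "vas_breathing"): 0.627,
        ("haq_di", "borg"): 0.546,
    }
    return CohortSpec(n=n, marginals=marginals, correlation_targets=targets, seed=seed)


def _transform_column(z: np.ndarray, marg: Marginal) -> np.ndarray:
    """Monotone map from a standard-normal latent to the marginal scale."""
    if isinstance(marg, BinaryMarginal):
        # increasing in z: positive level above the (1-p) latent quantile
        return z >= sps.norm.ppf(1.0 - marg.p)
    x = np.clip(marg.mean + marg.sd * z, marg.low, marg.high)
    if marg.integer:
        x = np.round(x)
    return x


def _numeric_transform(z: np.ndarray, marg: Marginal) -> np.ndarray:
    x = _transform_column(z, marg)
    return x.astype(float)


def nearest_correlation_matrix(A: np.ndarray, n_iter: int = 100, eig_floor: float = 1e-8) -> np.ndarray:
    """Higham-style alternating projections onto {PSD} and {unit diagonal}."""
    Y = A.copy()
    dS = np.zeros_like(A)
    for _ in range(n_iter):
        R = Y - dS
        w, V = np.linalg.eigh((R + R.T) / 2)
        X = (V * np.maximum(w, eig_floor)) @ V.T
        dS = X - R
        Y = X.copy()
        np.fill_diagonal(Y, 1.0)
        if np.min(np.linalg.eigvalsh(Y)) >= eig_floor / 2:
            break
    w, V = np.linalg.eigh((Y + Y.T) / 2)
    Y = (V * np.maximum(w, eig_floor)) @ V.T
    d = np.sqrt(np.diag(Y))
    Y = Y / np.outer(d, d)
    np.fill_diagonal(Y, 1.0)
    return Y


_CALIBRATION_SEED = 20160301
_CALIBRATION_DRAWS = 400_000
_calibration_cache: dict = {}


def _mc_pair_correlation(
    rho: float, f_a: Callable, f_b: Callable, z1: np.ndarray, z2: np.ndarray
) -> float:
    y = rho * z1 + np.sqrt(max(1.0 - rho * rho, 0.0)) * z2
    a = f_a(z1)
    b = f_b(y)
    return float(np.corrcoef(a, b)[0, 1])


def _calibrate_pair(target: float, marg_a: Marginal, marg_b: Marginal,
                    z1: np.ndarray, z2: np.ndarray) -> float:
    """Latent correlation whose post-transform Pearson r equals the target."""
    if target == 0.0:
        return 0.0
    f_a = lambda z: _numeric_transform(z, marg_a)
    f_b = lambda z: _numeric_transform(z, marg_b)

    def g(rho: float) -> float:
        return _mc_pair_correlation(rho, f_a, f_b, z1, z2) - target

    lo, hi = -0.9999, 0.9999
    if g(lo) > 0 or g(hi) < 0:
        raise ValueError(f"correlation target {target} not achievable under the marginals")
    return float(optimize.brentq(g, lo, hi, xtol=1e-4))


@dataclasses.dataclass
class CalibratedCopula:
    names: list[str]
    latent: np.ndarray  # PSD latent correlation matrix
    effective: dict[tuple[str, str], float]  # achieved Pearson r per targeted pair


def calibrate_copula(spec: CohortSpec) -> CalibratedCopula:
    """Calibrate latent pairwise correlations and repair to PSD.

    The Monte-Carlo calibration uses a fixed internal seed (common random
    numbers), so it is part of the model, independent of the sampling seed.
    """
    names = list(spec.marginals)
    key = (
        tuple(sorted((a, b, r) for (a, b), r in spec.correlation_targets.items())),
        tuple((n, spec.marginals[n]) for n in names),
    )
    if key in _calibration_cache:
        return _calibration_cache[key]

    rng = np.random.default_rng(_CALIBRATION_SEED)
    z1 = rng.standard_normal(_CALIBRATION_DRAWS)
    z2 = rng.standard_normal(_CALIBRATION_DRAWS)

    idx = {n: i for i, n in enumerate(names)}
    d = len(names)

    # Repair the *target* matrix first so infeasible presets become a
    # well-defined effective demand before latent calibration.
    T = np.eye(d)
    for (a, b), r in spec.correlation_targets.items():
        T[idx[a], idx[b]] = T[idx[b], idx[a]] = r
    if np.min(np.linalg.eigvalsh(T)) < 0:
        T = nearest_correlation_matrix(T)

    L = np.eye(d)
    for i in range(d):
        for j in range(i + 1, d):
            if T[i, j] != 0.0:
                L[i, j] = L[j, i] = _calibrate_pair(
                    T[i, j], spec.marginals[names[i]], spec.marginals[names[j]], z1, z2
                )
    if np.min(np.linalg.eigvalsh(L)) < 1e-10:
        L = nearest_correlation_matrix(L)

    effective: dict[tuple[str, str], float] = {}
    for (a, b) in spec.correlation_targets:
        i, j = idx[a], idx[b]
        effective[(a, b)] = _mc_pair_correlation(
            L[i, j],
            lambda z, m=spec.marginals[a]: _numeric_transform(z, m),
            lambda z, m=spec.marginals[b]: _numeric_transform(z, m),
            z1,
            z2,
        )
    out = CalibratedCopula(names=names, latent=L, effective=effective)
    _calibration_cache[key] = out
    return out


def generate_cohort_frame(spec: CohortSpec) -> pd.DataFrame:
    """Sample a cohort as a DataFrame (one column per marginal)."""
    if spec.n < 1:
        raise ValueError("n must be >= 1")
    cal = calibrate_copula(spec)
    rng = np.random.default_rng(spec.seed)
    w, V = np.linalg.eigh(cal.latent)
    root = V * np.sqrt(np.maximum(w, 0.0))
    Z = rng.standard_normal((spec.n, len(cal.names))) @ root.T
    data = {}
    for j, name in enumerate(cal.names):
        marg = spec.marginals[name]
        col = _transform_column(Z[:, j], marg)
        if isinstance(marg, BinaryMarginal):
            neg, pos = marg.levels
            col = np.where(col, pos, neg) if not isinstance(pos, bool) else col
        data[name] = col
    frame = pd.DataFrame(data)
    frame.insert(0, "id", [f"P{i + 1:04d}" for i in range(spec.n)])
    return frame


def generate_cohort(spec: CohortSpec) -> list[PatientRecord]:
    """Sample a cohort of fully populated patient records.

    Requires the default field set (see :func:`default_cohort_spec`); the
    CoVR total is split into extent and severity components at the preset
    mean ratio so that extent + severity = total.
    """
    frame = generate_cohort_frame(spec)
    required = set(default_cohort_spec().marginals)
    missing = required - set(frame.columns)
    if missing:
        raise ValueError(f"spec lacks marginals for record fields: {sorted(missing)}")
    records = []
    for _, row in frame.iterrows():
        total = float(row["covr_total"])
        # split at the preset mean ratio, keeping both components in [0, 15]
        extent = float(np.clip(total * _EXTENT_SHARE, max(total - 15.0, 0.0), 15.0))
        records.append(
            PatientRecord(
                id=row["id"],
                age=float(row["age"]),
                sex=str(row["sex"]),
                subtype=str(row["subtype"]),
                disease_duration=float(row["disease_duration"]),
                mrss=int(row["mrss"]),
                borg=float(row["borg"]),
                vas_breathing=float(row["vas_breathing"]),
                haq_di=float(row["haq_di"]),
                anti_topo_I=bool(row["anti_topo_I"]),
                anti_centromere=bool(row["anti_centromere"]),
                dlco_pct=float(row["dlco_pct"]),
                fvc_pct=float(row["fvc_pct"]),
                covr_extent=extent,
                covr_severity=float(row["covr_total"]) - extent,
                covr_total=float(row["covr_total"]),
                cam_fibrosis_pct=float(row["cam_fibrosis_pct"]),
            )
        )
    return records


def validate_record(record: PatientRecord) -> None:
    """Raise if any bounded field falls outside its scale."""
    for field, (low, high) in RECORD_BOUNDS.items():
        value = float(getattr(record, field))
        if not low <= value <= high:
            raise ValueError(f"{field}={value} outside [{low}, {high}] for {record.id}")
    if record.sex not in ("F", "M"):
        raise ValueError(f"invalid sex {record.sex!r}")
    if record.subtype not in ("dcSSc", "lcSSc"):
        raise ValueError(f"invalid subtype {record.subtype!r}")
    if not 0.0 <= record.covr_extent <= 15.0 or not 0.0 <= record.covr_severity <= 15.0:
        raise ValueError("CoVR components outside [0, 15]")


def cohort_to_frame(records: Sequence[PatientRecord]) -> pd.DataFrame:
    return pd.DataFrame([dataclasses.asdict(r) for r in records])
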