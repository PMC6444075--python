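"""Synthetic cohorts with controllable copula dependence and linked survival.

Each subgroup draws paired voxel values through a Gaussian copula: a
bivariate standard normal with correlation ``rho`` is mapped to uniforms by
the normal CDF and then to ADC/rCBV values by inverse-CDF of the marginal
distributions. ``rho`` spans the observed spectrum of joint-distribution
archetypes — near 0 gives a near-uniform copula matrix (low interdependence),
near 1 a diagonalized one (high interdependence). The default three-subgroup
cohort mirrors the reported glioblastoma subtypes: rho 0.05 / 0.45 / 0.90
with cohort proportions 35% / 42% / 23% and subgroup-linked overall-survival
medians of 400 / 550 / 400 days.

Marginals default to plausible NAWM-normalized values (ADC ~ Normal(1.3,
0.25) truncated at 0, rCBV ~ LogNormal(log 2.5, 0.5)); their exact shape is
irrelevant to the copula method by monotone invariance and exists only so
fixtures look like imaging data. Survival times are exponential (constant
hazard), which makes the true log hazard ratio between subgroups analytically
known; censoring is independent Uniform(0, b) with b solved so the expected
censored fraction matches ``censoring_rate``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd
import scipy.stats
from scipy.optimize import brentq

from .imaging_io import VoxelPairSample

_LN2 = float(np.log(2.0))


def default_adc_marginal():
    """NAWM-normalized ADC: Normal(1.3, 0.25) truncated below at 0."""
    return scipy.stats.truncnorm(a=-1.3 / 0.25, b=np.inf, loc=1.3, scale=0.25)


def default_rcbv_marginal():
    """NAWM-normalized rCBV: LogNormal with median 2.5, log-sd 0.5."""
    return scipy.stats.lognorm(s=0.5, scale=2.5)


@dataclass
class SubgroupSpec:
    """Generation recipe for one patient subgroup."""

    name: str
    dependence_rho: float
    n_patients: int
    voxels_per_patient: int = 3000
    adc_marginal: object = field(default_factory=default_adc_marginal)
    rcbv_marginal: object = field(default_factory=default_rcbv_marginal)
    survival_median_days: float = 450.0
    censoring_rate: float = 0.2

    def __post_init__(self) -> None:
        if not -1.0 <= self.dependence_rho <= 1.0:
            raise ValueError("dependence_rho must lie in [-1, 1]")
        if self.n_patients < 1 or self.voxels_per_patient < 1:
            raise ValueError("counts must be >= 1")
        if not 0.0 <= self.censoring_rate < 1.0:
            raise ValueError("censoring_rate must lie in [0, 1)")
        if self.survival_median_days <= 0:
            raise ValueError("survival_median_days must be positive")


@dataclass
class SyntheticCohort:
    """A generated cohort: voxel samples, truth labels, and a clinical table."""

    samples: list[VoxelPairSample]
    truth_labels: pd.Series  # patient_id -> subgroup name
    clinical: pd.DataFrame
    seed: int
    specs: list[SubgroupSpec]

    @property
    def n_patients(self) -> int:
        return len(self.samples)


def default_cohort_specs(
    n_total: int = 115, censoring_rate: float = 0.2, voxels_per_patient: int = 3000
) -> list[SubgroupSpec]:
    """Three-subgroup recipe mirroring the reported cohort structure.

    Proportions 35/42/23%: a low-interdependence subgroup (rho 0.05, the
    "most uniform" archetype), an intermediate one (rho 0.45) with the best
    survival, and a high-interdependence one (rho 0.90, "most diagonalized").
    """
    counts = {"I": int(round(0.35 * n_total)), "II": int(round(0.42 * n_total))}
    counts["III"] = n_total - counts["I"] - counts["II"]
    rhos = {"I": 0.05, "II": 0.45, "III": 0.90}
    medians = {"I": 400.0, "II": 550.0, "III": 400.0}
    return [
        SubgroupSpec(
            name=k,
            dependence_rho=rhos[k],
            n_patients=counts[k],
            voxels_per_patient=voxels_per_patient,
            survival_median_days=medians[k],
            censoring_rate=censoring_rate,
        )
        for k in ("I", "II", "III")
    ]


def sample_patient(
    spec: SubgroupSpec, seed: int | np.random.Generator, patient_id: str = "P0"
) -> VoxelPairSample:
    """Draw one patient's paired voxel sample through the Gaussian copula."""
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    n = spec.voxels_per_patient
    rho = spec.dependence_rho
    z1 = rng.standard_normal(n)
    z2 = rho * z1 + np.sqrt(max(0.0, 1.0 - rho**2)) * rng.standard_normal(n)
    u = scipy.stats.norm.cdf(z1)
    v = scipy.stats.norm.cdf(z2)
    adc = spec.adc_marginal.ppf(u)
    rcbv = spec.rcbv_marginal.ppf(v)
    if not (np.all(np.isfinite(adc)) and np.all(np.isfinite(rcbv))):
        raise ValueError("marginal inverse-CDF produced non-finite values")
    return VoxelPairSample(adc=adc, rcbv=rcbv, patient_id=patient_id)


def _censor_bound(rate: float, hazard: float) -> float:
    """Uniform(0,b) upper bound giving expected censored fraction ``rate``.

    For T ~ Exp(hazard) and C ~ U(0,b), P(C < T) = (1 - exp(-hazard*b)) /
    (hazard*b); solve for b.
    """
    if rate <= 0:
        return np.inf
    f = lambda x: (1.0 - np.exp(-x)) / x - rate
    x = brentq(f, 1e-9, 1e9)
    return x / hazard


def _simulate_survival(
    spec: SubgroupSpec, n: int, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    hazard = _LN2 / spec.survival_median_days
    t = rng.exponential(1.0 / hazard, size=n)
    if spec.censoring_rate > 0:
        c = rng.uniform(0.0, _censor_bound(spec.censoring_rate, hazard), size=n)
    else:
        c = np.full(n, np.inf)
    time = np.minimum(t, c)
    event = (t <= c).astype(int)
    return time, event


def sample_cohort(
    specs: list[SubgroupSpec], seed: int
) -> SyntheticCohort:
    """Generate a full cohort: voxel pairs, truth labels, clinical table.

    Clinical covariates (age, sex, extent of resection, MGMT, IDH, tumor
    volume) are drawn independently of subgroup with glioblastoma-plausible
    frequencies, so subgroup is the only survival-linked factor by
    construction. Fully deterministic for a fixed (specs, seed).
    """
    if not specs:
        raise ValueError("need at least one SubgroupSpec")
    rng = np.random.default_rng(seed)
    samples: list[VoxelPairSample] = []
    rows = []
    idx = 0
    for spec in specs:
        times, events = _simulate_survival(spec, spec.n_patients, rng)
        # PFS proportional to OS at roughly the reported median ratio
        pfs_t, pfs_e = _simulate_survival(
            SubgroupSpec(
                name=spec.name,
                dependence_rho=spec.dependence_rho,
                n_patients=spec.n_patients,
                survival_median_days=0.65 * spec.survival_median_days,
                censoring_rate=spec.censoring_rate,
            ),
            spec.n_patients,
            rng,
        )
        for i in range(spec.n_patients):
            pid = f"P{idx:03d}"
            idx += 1
            samples.append(sample_patient(spec, rng, patient_id=pid))
            rows.append(
                {
                    "patient_id": pid,
                    "subgroup_true": spec.name,
                    "time_days": times[i],
                    "event": events[i],
                    "pfs_days": pfs_t[i],
                    "pfs_event": pfs_e[i],
                    "age": float(np.clip(rng.normal(60.0, 10.0), 22.0, 80.0)),
                    "sex_male": int(rng.random() < 0.7),
                    "extent_of_resection": int(rng.random() < 0.67),
                    "mgmt_methylated": int(rng.random() < 0.42),
                    "idh_mutant": int(rng.random() < 0.06),
                    "tumor_volume_cm3": float(np.clip(rng.normal(48.0, 30.0), 5.0, 150.0)),
                }
            )
    clinical = pd.DataFrame(rows)
    truth = clinical.set_index("patient_id")["subgroup_true"]
    return SyntheticCohort(
        samples=samples, truth_labels=truth, clinical=clinical,
        seed=seed, specs=list(specs),
    )


def _pack_volumes(
    sample: VoxelPairSample,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Pack one patient's voxel pairs into small 3-D volumes.

    The tumor mask covers the first n voxels (lexicographic order) of a
    cube-ish block; the NAWM mask is a disjoint slab filled with the constant
    1.0 so the NAWM mean is exactly 1 and normalization is the identity.
    """
    n = sample.n_voxels
    side = max(2, int(np.ceil(n ** (1.0 / 3.0))))
    shape = (side + 4, side, side)
    adc_vol = np.zeros(shape)
    rcbv_vol = np.zeros(shape)
    tumor = np.zeros(shape, dtype=np.uint8)
    nawm = np.zeros(shape, dtype=np.uint8)
    flat = np.zeros(side**3, dtype=bool)
    flat[:n] = True
    block = flat.reshape(side, side, side)
    tumor[:side][block] = 1
    adc_block = np.zeros(side**3)
    adc_block[:n] = sample.adc
    rcbv_block = np.zeros(side**3)
    rcbv_block[:n] = sample.rcbv
    adc_vol[:side] = adc_block.reshape(side, side, side)
    rcbv_vol[:side] = rcbv_block.reshape(side, side, side)
    nawm[side + 1: side + 3] = 1
    adc_vol[side + 1: side + 3] = 1.0
    rcbv_vol[side + 1: side + 3] = 1.0
    return adc_vol, rcbv_vol, tumor, nawm


def write_fixture_images(cohort: SyntheticCohort, out_dir: str | Path) -> Path:
    """Write each patient's maps and masks as NIfTI files plus a manifest CSV.

    Also writes ``clinical.csv`` (including truth labels) next to the
    manifest. Returns the manifest path.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    affine = np.eye(4)
    rows = []
    for sample in cohort.samples:
        pid = sample.patient_id
        adc_vol, rcbv_vol, tumor, nawm = _pack_volumes(sample)
        paths = {}
        for tag, arr in (
            ("adc", adc_vol), ("rcbv", rcbv_vol),
            ("tumor_mask", tumor), ("nawm_mask", nawm),
        ):
            p = out_dir / f"{pid}_{tag}.nii"
            nib.save(nib.Nifti1Image(arr.astype(np.float64), affine), str(p))
            paths[f"{tag}_path"] = str(p)
        rows.append({"patient_id": pid, **paths})
    manifest = pd.DataFrame(rows)
    manifest_path = out_dir / "manifest.csv"
    manifest.to_csv(manifest_path, index=False)
    cohort.clinical.to_csv(out_dir / "clinical.csv", index=False)
    return manifest_path
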