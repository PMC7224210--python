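"""Seeded synthetic CT cohorts with blob-like nodules and multi-rater scores.

The generator emulates the structure of a multi-patient chest-CT nodule
cohort: each patient volume contains one or more blob-like nodules; each
nodule carries a ground-truth benign/malignant label and a handful of noisy
integer malignancy ratings (1-5) from 1-4 simulated raters, mirroring how
multi-radiologist collections score nodules.

Malignancy manifests in three controllable ways:

* **size** — malignant radii are drawn from a higher range than benign ones;
* **margin texture** — malignant blob boundaries are perturbed by a radial
  sinusoid (spiculation), benign blobs stay smooth;
* **context** — malignant nodules may be surrounded by a faint spherical
  shell 10-20 voxels outside the blob, which only the coarser patch scales
  can see. This gives multi-scale fusion genuinely scale-specific signal.

Rater noise and appearance share a latent *ambiguity* factor: a nodule whose
simulated raters land near the indeterminate midpoint (mean latent score
close to 3) is also rendered closer to the class boundary — its radius is
pulled toward the inter-class midpoint and, for malignant nodules, its
spiculation and context ring fade. With ``rating_noise_sd = 0`` the factor
is exactly 1 and appearance reduces to the pure class-conditional draw.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import gaussian_filter

from .containers import CTVolume, NoduleGroundTruth
from .errors import PlacementError

_MAX_PLACEMENT_TRIES = 500


@dataclass
class SyntheticConfig:
    """All knobs of the cohort generator; defaults define the study conditions."""

    n_patients: int = 20
    nodules_per_patient_range: tuple[int, int] = (1, 4)
    volume_shape: tuple[int, int, int] = (160, 160, 32)
    benign_radius_range: tuple[float, float] = (4.0, 6.0)
    malignant_radius_range: tuple[float, float] = (8.0, 11.0)
    spiculation_strength: float = 2.0        # boundary perturbation amplitude, voxels
    context_ring: bool = True                # faint shell outside malignant blobs
    ring_offset_range: tuple[float, float] = (10.0, 14.0)   # voxels beyond the blob radius
    ring_intensity: float = 0.3              # relative to blob intensity 1.0
    rater_count_distribution: tuple[float, float, float, float] = (0.15, 0.25, 0.3, 0.3)
    rating_noise_sd: float = 0.9
    background_noise_sd: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_patients < 1:
            raise ValueError("n_patients must be positive")
        lo, hi = self.nodules_per_patient_range
        if not (1 <= lo <= hi):
            raise ValueError("nodules_per_patient_range must be a non-empty range >= 1")
        if any(s < 8 for s in self.volume_shape):
            raise ValueError("volume_shape axes must be at least 8 voxels")
        for name in ("benign_radius_range", "malignant_radius_range", "ring_offset_range"):
            a, b = getattr(self, name)
            if not (0 < a <= b):
                raise ValueError(f"{name} must be a positive, ordered interval")
        if max(self.benign_radius_range[1], self.malignant_radius_range[1]) * 2 >= min(
            self.volume_shape[:2]
        ):
            raise ValueError("radius ranges exceed in-plane volume bounds")
        if self.spiculation_strength < 0 or self.rating_noise_sd < 0:
            raise ValueError("spiculation_strength and rating_noise_sd must be >= 0")
        p = np.asarray(self.rater_count_distribution, dtype=float)
        if p.shape != (4,) or np.any(p < 0) or not np.isclose(p.sum(), 1.0):
            raise ValueError("rater_count_distribution must be 4 probabilities summing to 1")


@dataclass
class Cohort:
    """A generated cohort plus its patient-disjoint train/test split."""

    config: SyntheticConfig
    volumes: list[CTVolume]
    nodules: list[NoduleGroundTruth]
    train_patients: list[str]
    test_patients: list[str]

    def nodules_of(self, patient_id: str) -> list[NoduleGroundTruth]:
        return [n for n in self.nodules if n.patient_id == patient_id]

    def volume_of(self, patient_id: str) -> CTVolume:
        for v in self.volumes:
            if v.patient_id == patient_id:
                return v
        raise KeyError(patient_id)

    @property
    def train_nodules(self) -> list[NoduleGroundTruth]:
        ids = set(self.train_patients)
        return [n for n in self.nodules if n.patient_id in ids]

    @property
    def test_nodules(self) -> list[NoduleGroundTruth]:
        ids = set(self.test_patients)
        return [n for n in self.nodules if n.patient_id in ids]


def _latent_ratings(
    true_label: int, config: SyntheticConfig, rng: np.random.Generator
) -> tuple[np.ndarray, list[int]]:
    """Draw latent rater scores and their rounded/clipped 1-5 ratings."""
    n_raters = int(rng.choice([1, 2, 3, 4], p=np.asarray(config.rater_count_distribution)))
    base = 4.5 if true_label == 1 else 1.5
    latent = base + config.rating_noise_sd * rng.standard_normal(n_raters)
    # round half up, then clip into the 1-5 scale
    ratings = np.clip(np.floor(latent + 0.5), 1, 5).astype(int)
    return latent, ratings.tolist()


def simulate_ratings(
    truth: NoduleGroundTruth, config: SyntheticConfig, rng_seed: int
) -> list[int]:
    """Simulate 1-4 noisy integer malignancy ratings for one nodule.

    Each rater perceives a latent score of 1.5 (benign) or 4.5 (malignant)
    plus Gaussian noise of sd ``rating_noise_sd``; the report is that score
    rounded to the nearest integer (half up) and clipped to [1, 5]. The
    number of raters is drawn from ``rater_count_distribution``.
    """
    rng = np.random.default_rng(rng_seed)
    _, ratings = _latent_ratings(truth.true_label, config, rng)
    return ratings


def _ambiguity_extremity(latent: np.ndarray) -> float:
    """How far the mean latent rater score sits from the indeterminate midpoint 3.

    1.0 for a textbook-clear nodule (mean latent at 1.5 or 4.5), 0.0 when the
    raters as a group are exactly on the fence.
    """
    return float(np.clip(abs(float(np.mean(latent)) - 3.0) / 1.5, 0.0, 1.0))


def _rasterize_blob(
    sub_shape: tuple[int, int, int],
    center: tuple[float, float, float],
    radius: float,
    axes_scale: tuple[float, float, float],
    spic_amplitude: float,
    spic_freqs: tuple[int, int],
    spic_phases: tuple[float, float],
) -> np.ndarray:
    """Indicator of a (possibly spiculated) ellipsoid, Gaussian-smoothed."""
    x, y, z = np.meshgrid(
        *(np.arange(s, dtype=float) - c for s, c in zip(sub_shape, center)), indexing="ij"
    )
    ax, ay, az = (radius * a for a in axes_scale)
    rho = np.sqrt((x / ax) ** 2 + (y / ay) ** 2 + (z / az) ** 2)
    if spic_amplitude > 0:
        theta = np.arctan2(y, x)
        r = np.sqrt(x * x + y * y + z * z)
        phi = np.arccos(np.clip(np.divide(z, r, out=np.zeros_like(r), where=r > 0), -1, 1))
        ripple = np.sin(spic_freqs[0] * theta + spic_phases[0]) * np.cos(
            spic_freqs[1] * phi + spic_phases[1]
        )
        thresh = 1.0 + (spic_amplitude / radius) * ripple
    else:
        thresh = 1.0
    blob = (rho <= thresh).astype(float)
    return gaussian_filter(blob, sigma=1.0)


def generate_nodule_volume(
    config: SyntheticConfig, patient_id: str, rng_seed: int
) -> tuple[CTVolume, list[NoduleGroundTruth]]:
    """Generate one patient volume with non-overlapping synthetic nodules.

    Returns the volume and the per-nodule ground truth; the truth records
    carry the simulated rater scores. Bit-identical under a repeated seed.

    Raises
    ------
    PlacementError
        If the volume cannot host the requested number of nodules at the
        required pairwise separation.
    """
    rng = np.random.default_rng(rng_seed)
    nx, ny, nz = config.volume_shape
    vol = rng.normal(0.0, config.background_noise_sd, size=config.volume_shape)

    lo, hi = config.nodules_per_patient_range
    n_nodules = int(rng.integers(lo, hi + 1))

    b_lo, b_hi = config.benign_radius_range
    m_lo, m_hi = config.malignant_radius_range
    class_midpoint = 0.5 * ((b_lo + b_hi) / 2 + (m_lo + m_hi) / 2)
    # worst-case in-plane half-extent of a blob: radius + spiculation + smoothing
    max_half_ext = max(b_hi, m_hi) * 1.15 + config.spiculation_strength + 3
    margin = max_half_ext + 21  # the coarsest patch scale adds 20 px per side

    truths: list[NoduleGroundTruth] = []
    placed: list[tuple[float, float, float, float]] = []
    for k in range(n_nodules):
        true_label = int(rng.integers(0, 2))
        rating_seed = int(rng.integers(0, 2**31 - 1))
        latent, ratings = _latent_ratings(
            true_label, config, np.random.default_rng(rating_seed)
        )
        extremity = _ambiguity_extremity(latent)

        r_draw = rng.uniform(*(config.malignant_radius_range if true_label else config.benign_radius_range))
        radius = class_midpoint + extremity * (r_draw - class_midpoint)
        axes_scale = (rng.uniform(0.85, 1.15), rng.uniform(0.85, 1.15), rng.uniform(0.45, 0.7))
        # keep the blob within the thin z extent of the volume
        axes_scale = (axes_scale[0], axes_scale[1], min(axes_scale[2], (nz / 2 - 3) / radius))
        spic_amp = config.spiculation_strength * extremity if true_label else 0.0
        spic_freqs = (int(rng.integers(4, 8)), int(rng.integers(3, 6)))
        spic_phases = (rng.uniform(0, 2 * np.pi), rng.uniform(0, 2 * np.pi))
        ring_offset = rng.uniform(*config.ring_offset_range)

        if 2 * margin >= min(nx, ny):
            raise PlacementError(
                f"volume in-plane size {(nx, ny)} too small for nodule half-extent "
                f"{max_half_ext:.1f} plus the 20-px scale-3 margin"
            )
        half_ext = radius * max(axes_scale[:2]) + spic_amp + 3
        z_half = radius * axes_scale[2] + 2
        # keep each neighbour's blob out of this nodule's coarsest crop
        for attempt in range(_MAX_PLACEMENT_TRIES + 1):
            cx = float(rng.uniform(margin, nx - margin))
            cy = float(rng.uniform(margin, ny - margin))
            cz = float(rng.uniform(max(z_half, 2.0), nz - max(z_half, 2.0)))
            if all(
                (cx - px) ** 2 + (cy - py) ** 2 >= (half_ext + ph + 26) ** 2
                for px, py, _, ph in placed
            ):
                break
            if attempt == _MAX_PLACEMENT_TRIES:
                raise PlacementError(
                    f"could not place nodule {k + 1}/{n_nodules} in a "
                    f"{(nx, ny, nz)} volume without overlapping patch footprints"
                )
        placed.append((cx, cy, cz, half_ext))

        # rasterize into a local window around the center
        w_xy = int(np.ceil(half_ext + (ring_offset + 2 if config.context_ring else 0) + 3))
        w_z = nz  # thin axis: rasterize full depth, the window is cheap
        x0 = max(int(np.floor(cx)) - w_xy, 0)
        x1 = min(int(np.floor(cx)) + w_xy + 1, nx)
        y0 = max(int(np.floor(cy)) - w_xy, 0)
        y1 = min(int(np.floor(cy)) + w_xy + 1, ny)
        local_center = (cx - x0, cy - y0, cz)
        blob = _rasterize_blob(
            (x1 - x0, y1 - y0, w_z), local_center, radius, axes_scale,
            spic_amp, spic_freqs, spic_phases,
        )
        vol[x0:x1, y0:y1, :] += blob

        if config.context_ring and true_label == 1:
            lx, ly, lz = np.meshgrid(
                np.arange(x1 - x0, dtype=float) - local_center[0],
                np.arange(y1 - y0, dtype=float) - local_center[1],
                np.arange(w_z, dtype=float) - local_center[2],
                indexing="ij",
            )
            dist = np.sqrt(lx**2 + ly**2 + lz**2)
            ring_r = radius + ring_offset
            shell = np.exp(-0.5 * ((dist - ring_r) / 1.2) ** 2)
            vol[x0:x1, y0:y1, :] += config.ring_intensity * extremity * shell

        # tight integer bbox around the smoothed blob support
        bx = int(np.ceil(half_ext))
        bz = int(np.ceil(z_half))
        ci = (int(round(cx)), int(round(cy)), int(round(cz)))
        bbox = (
            max(ci[0] - bx, 0), min(ci[0] + bx + 1, nx),
            max(ci[1] - bx, 0), min(ci[1] + bx + 1, ny),
            max(ci[2] - bz, 0), min(ci[2] + bz + 1, nz),
        )
        ellipsoid_vol = 4.0 / 3.0 * np.pi * radius**3 * float(np.prod(axes_scale))
        truths.append(
            NoduleGroundTruth(
                nodule_id=f"{patient_id}-n{k}",
                patient_id=patient_id,
                center=ci,
                bbox=bbox,
                true_label=true_label,
                true_volume=ellipsoid_vol,
                true_diameter=(6.0 * ellipsoid_vol / np.pi) ** (1.0 / 3.0),
                ratings=ratings,
            )
        )

    return CTVolume(vol.astype(np.float32), patient_id=patient_id), truths


def split_patients(
    patient_ids: list[str], seed: int, train_fraction: float = 0.7
) -> tuple[list[str], list[str]]:
    """Patient-disjoint split, train fraction rounded to the nearest count."""
    if len(patient_ids) < 2:
        raise ValueError("need at least 2 patients to form a disjoint split")
    rng = np.random.default_rng(seed)
    order = list(np.array(patient_ids)[rng.permutation(len(patient_ids))])
    n_train = int(np.floor(len(order) * train_fraction + 0.5))
    n_train = min(max(n_train, 1), len(order) - 1)
    return sorted(order[:n_train]), sorted(order[n_train:])


def generate_cohort(config: SyntheticConfig) -> Cohort:
    """Generate a full cohort and its 70/30 patient-disjoint split."""
    if config.n_patients < 2:
        raise ValueError("n_patients must be >= 2 to form a patient-disjoint split")
    ss = np.random.SeedSequence(config.seed)
    patient_seeds = ss.generate_state(config.n_patients + 1)
    volumes, nodules = [], []
    for i in range(config.n_patients):
        pid = f"P{i:03d}"
        # a dense draw can fail placement; retry with derived seeds (deterministic)
        for retry in range(5):
            try:
                vol, truths = generate_nodule_volume(
                    config, pid, int((patient_seeds[i] + retry * 7919) % (2**31 - 1))
                )
                break
            except PlacementError:
                if retry == 4:
                    raise
        volumes.append(vol)
        nodules.extend(truths)
    train_ids, test_ids = split_patients(
        [v.patient_id for v in volumes], int(patient_seeds[-1] % (2**31 - 1))
    )
    return Cohort(config, volumes, nodules, train_ids, test_ids)
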