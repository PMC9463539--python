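"""Simulation of a multi-reader radiograph annotation panel.

This module generates radiograph-like grayscale images with known ground
truth, simulates a panel of human readers with heterogeneous per-reader
confusion matrices and age-dependent reliability, and derives a final
label per image through an arbitration protocol modelled on multi-site
epidemiological CXR studies:

* every image is read independently by the two *initial* readers of its
  site;
* if they disagree, two *arbitrators* drawn at random from the arbitrator
  pool each read the image;
* if the arbitrators also disagree, a consensus decision is simulated as
  a single draw from the average of the two arbitrators' (age-adjusted)
  confusion rows;
* 10% of initially-concordant images receive an additional quality-control
  read by a random arbitrator, which never changes the final label.

All randomness is driven by :class:`numpy.random.Generator` streams spawned
per image from a root seed, so datasets are bit-reproducible.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from enum import Enum
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import ndimage

from .labels import ClassLabel, CLASS_NAMES, N_CLASSES

__all__ = [
    "ReaderRole",
    "Phase",
    "Provenance",
    "ReaderProfile",
    "SynthImage",
    "AnnotationRecord",
    "FinalLabel",
    "DatasetSplit",
    "PanelDataset",
    "class_prior",
    "synth_image",
    "age_factor",
    "age_adjusted_row",
    "sample_reader_label",
    "reader_distinguishability",
    "most_distinguishable_pair",
    "arbitrate",
    "heterogeneous_profiles",
    "site_adjusted_priors",
    "build_panel_dataset",
    "split_by_patient",
]

#: Default class prevalence: consolidation, other infiltrate, both, normal,
#: uninterpretable (multi-site paediatric CXR study mix).
DEFAULT_PRIOR = (0.15, 0.24, 0.11, 0.40, 0.10)

#: Default site codes (seven-country study layout).  The last two default
#: sites receive a lower share of NORMAL images, mimicking the real-world
#: pattern where some sites see mostly abnormal films.
DEFAULT_SITES = ("KEN", "GAM", "THA", "MAL", "BAN", "SAF", "ZAM")
LOW_NORMAL_SITES = ("SAF", "ZAM")

QC_FRACTION = 0.10


class ReaderRole(str, Enum):
    INITIAL = "INITIAL"
    ARBITRATOR = "ARBITRATOR"


class Phase(str, Enum):
    INITIAL = "INITIAL"
    ARBITRATION = "ARBITRATION"
    CONSENSUS = "CONSENSUS"
    QC = "QC"


class Provenance(str, Enum):
    INITIAL_CONCORDANT = "INITIAL_CONCORDANT"
    ARBITRATOR_CONCORDANT = "ARBITRATOR_CONCORDANT"
    CONSENSUS = "CONSENSUS"


def class_prior(override: Sequence[float] | None = None) -> np.ndarray:
    """Return the class prevalence vector (a 5-simplex point).

    With no argument returns the default study prevalence
    ``(0.15, 0.24, 0.11, 0.40, 0.10)``.  An override is validated and
    returned verbatim.
    """
    prior = np.asarray(DEFAULT_PRIOR if override is None else override, dtype=float)
    if prior.shape != (N_CLASSES,):
        raise ValueError(f"prior must have {N_CLASSES} entries, got shape {prior.shape}")
    if np.any(prior < 0) or not math.isclose(float(prior.sum()), 1.0, abs_tol=1e-9):
        raise ValueError("prior must be nonnegative and sum to 1")
    return prior


def _validate_confusion(confusion: np.ndarray) -> np.ndarray:
    confusion = np.asarray(confusion, dtype=float)
    if confusion.shape != (N_CLASSES, N_CLASSES):
        raise ValueError(f"confusion matrix must be {N_CLASSES}x{N_CLASSES}")
    if np.any(confusion < 0) or np.any(confusion > 1):
        raise ValueError("confusion entries must lie in [0, 1]")
    rowsums = confusion.sum(axis=1)
    if np.any(np.abs(rowsums - 1.0) > 1e-9):
        raise ValueError(f"confusion rows must sum to 1 (got {rowsums})")
    return confusion


@dataclass(frozen=True)
class ReaderProfile:
    """A simulated reader: identity, role, and error model.

    ``confusion[t][o]`` is the probability the reader reports class ``o``
    when the true class is ``t``.  ``age_noise_slope`` controls how fast the
    reader's off-diagonal (error) mass shrinks with patient age; 0 disables
    the age effect.
    """

    reader_id: str
    role: ReaderRole
    confusion: np.ndarray
    age_noise_slope: float = 1.0

    def __post_init__(self) -> None:
        object.__setattr__(self, "confusion", _validate_confusion(self.confusion))

    def accuracy(self, prior: np.ndarray | None = None) -> float:
        """Prior-weighted probability of reporting the true class (age 0)."""
        prior = class_prior(prior)
        return float(prior @ np.diag(self.confusion))


@dataclass
class SynthImage:
    """A synthetic radiograph-like image with ground truth and ROI masks.

    ``blob_mask`` marks the dense consolidation blob (empty for classes
    without one) and is the ground-truth region of interest used to score
    saliency maps.  ``lung_mask`` marks the two elliptical lung fields.
    """

    image_id: str
    patient_id: str
    site: str
    age_months: float
    true_class: ClassLabel
    pixels: np.ndarray
    blob_mask: np.ndarray = field(repr=False, default=None)  # type: ignore[assignment]
    lung_mask: np.ndarray = field(repr=False, default=None)  # type: ignore[assignment]


@dataclass(frozen=True)
class AnnotationRecord:
    image_id: str
    reader_id: str
    label: ClassLabel
    phase: Phase


@dataclass(frozen=True)
class FinalLabel:
    image_id: str
    label: ClassLabel
    provenance: Provenance


@dataclass(frozen=True)
class DatasetSplit:
    """Patient-level train/test partition."""

    train_patients: frozenset[str]
    test_patients: frozenset[str]
    seed: int


# ---------------------------------------------------------------------------
# Image synthesis
# ---------------------------------------------------------------------------

def _ellipse_mask(size: int, cy: float, cx: float, ry: float, rx: float) -> np.ndarray:
    yy, xx = np.mgrid[0:size, 0:size]
    return ((yy - cy) / ry) ** 2 + ((xx - cx) / rx) ** 2 <= 1.0


def synth_image(
    true_class: ClassLabel,
    size: int,
    rng_seed: int,
    *,
    image_id: str = "img",
    patient_id: str = "pat",
    site: str = "S1",
    age_months: float = 24.0,
) -> SynthImage:
    """Render a deterministic radiograph-like image for a given class.

    The scene is a bright "thorax" background with two darker elliptical
    lung fields.  CONSOLIDATION adds a dense bright blob inside one lung
    field; OTHER_INFILTRATE adds diffuse mid-intensity texture within the
    lung fields; BOTH adds both; NORMAL adds neither; UNINTERPRETABLE
    flattens the scene with heavy blur and overlays occluding bands so the
    lung fields are not resolvable.
    """
    if size < 32:
        raise ValueError(f"image size must be >= 32, got {size}")
    true_class = ClassLabel(true_class)
    rng = np.random.default_rng(rng_seed)

    # thorax background with a mild vertical intensity gradient
    grad = np.linspace(0.78, 0.68, size)[:, None]
    img = np.repeat(grad, size, axis=1).astype(np.float64)

    left = _ellipse_mask(size, 0.48 * size, 0.30 * size, 0.32 * size, 0.17 * size)
    right = _ellipse_mask(size, 0.48 * size, 0.70 * size, 0.32 * size, 0.17 * size)
    lung_mask = left | right
    img[lung_mask] = 0.30

    blob_mask = np.zeros((size, size), dtype=bool)
    if true_class in (ClassLabel.CONSOLIDATION, ClassLabel.BOTH):
        # one dense bright blob inside a randomly chosen lung field
        host = left if rng.random() < 0.5 else right
        cx = 0.30 * size if host is left else 0.70 * size
        cy = rng.uniform(0.35, 0.60) * size
        cx = cx + rng.uniform(-0.04, 0.04) * size
        r = rng.uniform(0.11, 0.15) * size
        blob_mask = _ellipse_mask(size, cy, cx, r, r) & host
        img[blob_mask] = 0.85

    if true_class in (ClassLabel.OTHER_INFILTRATE, ClassLabel.BOTH):
        # diffuse mid-intensity texture across the lung fields
        texture = ndimage.gaussian_filter(rng.normal(0.0, 1.0, (size, size)), size / 24)
        texture = 0.18 * texture / (np.abs(texture).max() + 1e-12) + 0.22
        img = np.where(lung_mask & ~blob_mask, img + texture, img)

    img += rng.normal(0.0, 0.02, (size, size))

    if true_class is ClassLabel.UNINTERPRETABLE:
        img = ndimage.gaussian_filter(img, size / 8)
        img = 0.35 * (img - img.mean()) + img.mean()  # contrast collapse
        n_bands = 2 + int(rng.integers(0, 2))
        band_h = max(2, int(0.06 * size))
        for _ in range(n_bands):
            y0 = int(rng.integers(0, size - band_h))
            img[y0 : y0 + band_h, :] = 0.80
        lung_mask = np.zeros_like(lung_mask)

    img = np.clip(img, 0.0, 1.0).astype(np.float32)
    return SynthImage(
        image_id=image_id,
        patient_id=patient_id,
        site=site,
        age_months=age_months,
        true_class=true_class,
        pixels=img,
        blob_mask=blob_mask,
        lung_mask=lung_mask,
    )


# ---------------------------------------------------------------------------
# Reader behaviour
# ---------------------------------------------------------------------------

def age_factor(slope: float, age_months: float) -> float:
    """Multiplier applied to a reader's off-diagonal (error) mass.

    Decreases linearly with age and floors at 0.3, so agreement improves
    monotonically with patient age: ``max(0.3, 1 - slope * age/120)``.
    """
    if age_months < 0:
        raise ValueError("age_months must be nonnegative")
    return float(np.clip(1.0 - slope * age_months / 120.0, 0.3, 1.0))


def age_adjusted_row(
    profile: ReaderProfile, true_class: ClassLabel, age_months: float
) -> np.ndarray:
    """The reader's confusion row for ``true_class`` after age adjustment.

    Off-diagonal mass is scaled by :func:`age_factor` and the freed mass is
    returned to the diagonal, so the row remains a probability vector.
    """
    t = int(true_class)
    row = profile.confusion[t].copy()
    f = age_factor(profile.age_noise_slope, age_months)
    row_adj = row * f
    row_adj[t] = 1.0 - (row.sum() - row[t]) * f  # diagonal absorbs freed mass
    return row_adj


def sample_reader_label(
    profile: ReaderProfile,
    true_class: ClassLabel,
    age_months: float,
    rng: np.random.Generator,
) -> ClassLabel:
    """Draw one label from the reader's age-adjusted confusion row."""
    row = age_adjusted_row(profile, true_class, age_months)
    return ClassLabel(int(rng.choice(N_CLASSES, p=row)))


# ---------------------------------------------------------------------------
# Arbitration protocol
# ---------------------------------------------------------------------------

def arbitrate(
    initial: Sequence[AnnotationRecord],
    arbitrator_pool: Sequence[ReaderProfile],
    image: SynthImage,
    rng: np.random.Generator,
    *,
    qc_fraction: float = QC_FRACTION,
) -> tuple[FinalLabel, list[AnnotationRecord]]:
    """Resolve the final label for one image from its two initial reads.

    Concordant initial reads stand as the final label (with a 10%
    quality-control re-read that never alters it).  Discordant reads go to
    two distinct randomly chosen arbitrators; if they also disagree, the
    consensus discussion is simulated as a single draw from the average of
    the two arbitrators' age-adjusted confusion rows, recorded as a
    CONSENSUS-phase annotation for each of the two arbitrators.
    """
    if len(initial) != 2:
        raise ValueError(f"expected exactly 2 initial records, got {len(initial)}")
    if len(arbitrator_pool) < 2:
        raise ValueError("arbitration requires at least 2 arbitrators")
    image_id = initial[0].image_id
    if initial[1].image_id != image_id:
        raise ValueError("initial records refer to different images")

    extra: list[AnnotationRecord] = []
    if initial[0].label == initial[1].label:
        final = FinalLabel(image_id, initial[0].label, Provenance.INITIAL_CONCORDANT)
        if rng.random() < qc_fraction:
            qc_arb = arbitrator_pool[int(rng.integers(len(arbitrator_pool)))]
            qc_label = sample_reader_label(qc_arb, image.true_class, image.age_months, rng)
            extra.append(AnnotationRecord(image_id, qc_arb.reader_id, qc_label, Phase.QC))
        return final, extra

    idx = rng.choice(len(arbitrator_pool), size=2, replace=False)
    arbs = [arbitrator_pool[int(i)] for i in idx]
    arb_labels = []
    for arb in arbs:
        lab = sample_reader_label(arb, image.true_class, image.age_months, rng)
        arb_labels.append(lab)
        extra.append(AnnotationRecord(image_id, arb.reader_id, lab, Phase.ARBITRATION))

    if arb_labels[0] == arb_labels[1]:
        return FinalLabel(image_id, arb_labels[0], Provenance.ARBITRATOR_CONCORDANT), extra

    rows = [age_adjusted_row(a, image.true_class, image.age_months) for a in arbs]
    mean_row = (rows[0] + rows[1]) / 2.0
    consensus = ClassLabel(int(rng.choice(N_CLASSES, p=mean_row)))
    for arb in arbs:
        extra.append(AnnotationRecord(image_id, arb.reader_id, consensus, Phase.CONSENSUS))
    return FinalLabel(image_id, consensus, Provenance.CONSENSUS), extra


# ---------------------------------------------------------------------------
# Panel construction
# ---------------------------------------------------------------------------

def _contrasting_biases(
    rng: np.random.Generator, n: int, alpha: float = 0.25, max_cos: float = 0.10
) -> list[np.ndarray]:
    """Dirichlet preference vectors with pairwise-bounded cosine similarity.

    Each reader's errors concentrate in a characteristic direction; within a
    group the directions are forced apart so the readers remain mutually
    distinguishable from their labels alone.
    """
    biases: list[np.ndarray] = []
    attempts = 0
    while len(biases) < n:
        cand = rng.dirichlet(np.ones(N_CLASSES) * alpha)
        attempts += 1
        cos_ok = all(
            float(cand @ b) / (np.linalg.norm(cand) * np.linalg.norm(b)) <= max_cos
            for b in biases
        )
        if cos_ok or attempts > 200:
            biases.append(cand)
            attempts = 0
    return biases


def _biased_confusion(
    rng: np.random.Generator, diag_range: tuple[float, float], bias: np.ndarray
) -> np.ndarray:
    """Row-stochastic confusion matrix: per-class diagonal accuracy drawn
    from ``diag_range``; off-diagonal mass follows the reader's bias."""
    conf = np.zeros((N_CLASSES, N_CLASSES))
    for t in range(N_CLASSES):
        d = rng.uniform(*diag_range)
        off = bias.copy()
        off[t] = 0.0
        total = off.sum()
        if total <= 1e-12:
            off = np.full(N_CLASSES, 1.0 / (N_CLASSES - 1))
            off[t] = 0.0
            total = off.sum()
        conf[t] = (1.0 - d) * off / total
        conf[t, t] = d
    return conf


def heterogeneous_profiles(
    n_initial: int,
    n_arbitrators: int,
    seed: int | np.random.Generator = 0,
    *,
    initial_diag: tuple[float, float] = (0.40, 0.74),
    arbitrator_diag: tuple[float, float] = (0.59, 0.77),
    age_noise_slope: float = 1.0,
    site_skill_halfwidth: float = 0.06,
) -> list[ReaderProfile]:
    """Generate a panel of readers with distinct confusion matrices.

    Initial readers are noisier (per-class accuracy 0.40-0.74, the range
    reported for first-line readers in multi-site CXR panels) than
    arbitrators (0.59-0.77).  The two initial readers of a site (consecutive
    profiles) get comparable skill — a site-level accuracy is drawn and both
    readers' diagonals stay within ``site_skill_halfwidth`` of it — but
    contrasting error directions, so same-site readers disagree in
    characteristic, identifiable ways rather than merely differing in
    accuracy.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    profiles: list[ReaderProfile] = []
    biases = _contrasting_biases(rng, n_initial + n_arbitrators)
    lo, hi = initial_diag
    for s in range(n_initial // 2):
        site_skill = rng.uniform(lo + site_skill_halfwidth, hi - site_skill_halfwidth)
        band = (site_skill - site_skill_halfwidth, site_skill + site_skill_halfwidth)
        for j in range(2):
            k = 2 * s + j
            profiles.append(
                ReaderProfile(
                    reader_id=f"I{k + 1:02d}",
                    role=ReaderRole.INITIAL,
                    confusion=_biased_confusion(rng, band, biases[k]),
                    age_noise_slope=age_noise_slope,
                )
            )
    if n_initial % 2:  # odd leftover reader (not site-paired)
        profiles.append(
            ReaderProfile(
                reader_id=f"I{n_initial:02d}",
                role=ReaderRole.INITIAL,
                confusion=_biased_confusion(rng, initial_diag, biases[n_initial - 1]),
                age_noise_slope=age_noise_slope,
            )
        )
    for k in range(n_arbitrators):
        profiles.append(
            ReaderProfile(
                reader_id=f"A{k + 1:02d}",
                role=ReaderRole.ARBITRATOR,
                confusion=_biased_confusion(rng, arbitrator_diag, biases[n_initial + k]),
                age_noise_slope=age_noise_slope,
            )
        )
    return profiles


def reader_distinguishability(
    a: ReaderProfile,
    b: ReaderProfile,
    prior: np.ndarray | None = None,
    age_months: float = 30.0,
) -> tuple[float, float]:
    """Expected own-minus-other soft-agreement margins for two readers.

    For a predictor that reproduces reader ``a``'s (age-adjusted) confusion
    rows, the expected probability assigned to ``a``'s own labels exceeds
    that assigned to ``b``'s labels by
    ``sum_t pi_t  r_a[t] . (r_a[t] - r_b[t])``.  Both directed margins must
    be positive for the pair to be mutually distinguishable from labels
    alone; readers differing mainly in accuracy (not bias direction) can
    have one negative margin.
    """
    pi = class_prior(prior)
    ra = np.stack([age_adjusted_row(a, ClassLabel(t), age_months) for t in range(N_CLASSES)])
    rb = np.stack([age_adjusted_row(b, ClassLabel(t), age_months) for t in range(N_CLASSES)])
    m_a = float(pi @ np.sum(ra * (ra - rb), axis=1))
    m_b = float(pi @ np.sum(rb * (rb - ra), axis=1))
    return m_a, m_b


def most_distinguishable_pair(
    profiles: Sequence[ReaderProfile],
    prior: np.ndarray | None = None,
    age_months: float = 30.0,
) -> tuple[ReaderProfile, ReaderProfile]:
    """The reader pair maximizing the smaller directed margin.

    "Most dissimilar" in the sense that matters for identifiability: each
    member's labels must be better explained by its own confusion rows than
    by the other's.
    """
    import itertools

    best = None
    for a, b in itertools.combinations(profiles, 2):
        m_a, m_b = reader_distinguishability(a, b, prior, age_months)
        key = min(m_a, m_b)
        if best is None or key > best[0]:
            best = (key, a, b)
    if best is None:
        raise ValueError("need at least two profiles")
    return best[1], best[2]


def site_adjusted_priors(
    prior: np.ndarray, sites: Sequence[str], low_normal: Sequence[str] = LOW_NORMAL_SITES
) -> dict[str, np.ndarray]:
    """Per-site class priors: designated sites get a lower NORMAL share.

    For sites in ``low_normal`` the NORMAL probability is reduced to 70% of
    its base value and the freed mass is redistributed proportionally over
    the abnormal classes.
    """
    prior = class_prior(prior)
    out: dict[str, np.ndarray] = {}
    for site in sites:
        p = prior.copy()
        if site in low_normal and p[ClassLabel.NORMAL] > 0:
            freed = 0.3 * p[ClassLabel.NORMAL]
            p[ClassLabel.NORMAL] -= freed
            others = np.arange(N_CLASSES) != int(ClassLabel.NORMAL)
            p[others] += freed * prior[others] / prior[others].sum()
        out[site] = p / p.sum()
    return out


@dataclass
class PanelDataset:
    """A fully simulated panel-annotated image dataset."""

    images: list[SynthImage]
    annotations: list[AnnotationRecord]
    finals: list[FinalLabel]
    profiles: list[ReaderProfile]
    seed: int

    @property
    def reader_index(self) -> dict[str, int]:
        """Stable reader-id -> integer index map (model embedding rows)."""
        return {p.reader_id: i for i, p in enumerate(self.profiles)}

    @property
    def initial_profiles(self) -> list[ReaderProfile]:
        return [p for p in self.profiles if p.role is ReaderRole.INITIAL]

    @property
    def arbitrator_profiles(self) -> list[ReaderProfile]:
        return [p for p in self.profiles if p.role is ReaderRole.ARBITRATOR]

    def image_by_id(self, image_id: str) -> SynthImage:
        if not hasattr(self, "_index"):
            self._index = {im.image_id: im for im in self.images}
        return self._index[image_id]

    def final_by_id(self, image_id: str) -> FinalLabel:
        if not hasattr(self, "_findex"):
            self._findex = {f.image_id: f for f in self.finals}
        return self._findex[image_id]

    def manifest_frame(self) -> pd.DataFrame:
        """Long-format annotation manifest (one row per annotation record)."""
        meta = {im.image_id: im for im in self.images}
        roles = {p.reader_id: p.role.value for p in self.profiles}
        rows = []
        for rec in self.annotations:
            im = meta[rec.image_id]
            rows.append(
                {
                    "image_id": rec.image_id,
                    "patient_id": im.patient_id,
                    "site": im.site,
                    "age_months": im.age_months,
                    "reader_id": rec.reader_id,
                    "role": roles[rec.reader_id],
                    "phase": rec.phase.value,
                    "label": CLASS_NAMES[rec.label],
                    "true_class": CLASS_NAMES[im.true_class],
                }
            )
        return pd.DataFrame(rows)

    def finals_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "image_id": [f.image_id for f in self.finals],
                "label": [CLASS_NAMES[f.label] for f in self.finals],
                "provenance": [f.provenance.value for f in self.finals],
            }
        )


def build_panel_dataset(
    n_patients: int,
    images_per_patient_dist: Mapping[int, float] | None = None,
    n_initial_readers: int = 6,
    n_arbitrators: int = 2,
    prior: Sequence[float] | None = None,
    profiles: Sequence[ReaderProfile] | None = None,
    seed: int = 0,
    *,
    image_size: int = 64,
    site_prior_adjust: bool = True,
    age_range: tuple[float, float] = (1.0, 60.0),
    qc_fraction: float = QC_FRACTION,
) -> PanelDataset:
    """Simulate a complete multi-site, multi-reader annotated dataset.

    Patients are assigned a site and an age; each site contributes two
    initial readers who annotate every image from that site; discordant
    reads are arbitrated.  The default image-per-patient distribution gives
    ~4% of patients a second image.  Everything is reproducible from
    ``seed`` via per-image random substreams.
    """
    if n_initial_readers % 2 != 0 or n_initial_readers < 2:
        raise ValueError("n_initial_readers must be even and >= 2")
    if n_arbitrators < 2:
        raise ValueError("need at least 2 arbitrators")
    if images_per_patient_dist is None:
        images_per_patient_dist = {1: 0.96, 2: 0.04}

    if profiles is None:
        profiles = heterogeneous_profiles(
            n_initial_readers, n_arbitrators, np.random.default_rng(seed + 1)
        )
    profiles = list(profiles)
    initial = [p for p in profiles if p.role is ReaderRole.INITIAL]
    arbitrators = [p for p in profiles if p.role is ReaderRole.ARBITRATOR]
    if len(initial) != n_initial_readers or len(arbitrators) != n_arbitrators:
        raise ValueError(
            f"profiles must cover {n_initial_readers} initial readers and "
            f"{n_arbitrators} arbitrators (got {len(initial)}/{len(arbitrators)})"
        )

    n_sites = n_initial_readers // 2
    sites = [DEFAULT_SITES[i] if i < len(DEFAULT_SITES) else f"S{i + 1}" for i in range(n_sites)]
    site_readers = {site: (initial[2 * i], initial[2 * i + 1]) for i, site in enumerate(sites)}
    base_prior = class_prior(prior)
    if site_prior_adjust:
        priors = site_adjusted_priors(base_prior, sites)
    else:
        priors = {s: base_prior for s in sites}

    root = np.random.SeedSequence(seed)
    ss_assign, ss_images = root.spawn(2)
    rng = np.random.default_rng(ss_assign)

    counts = np.array(sorted(images_per_patient_dist))
    probs = np.array([images_per_patient_dist[int(c)] for c in counts], dtype=float)
    probs = probs / probs.sum()

    patient_site = rng.choice(len(sites), size=n_patients)
    patient_age = rng.uniform(age_range[0], age_range[1], size=n_patients)
    patient_nimg = counts[rng.choice(len(counts), size=n_patients, p=probs)]
    n_images = int(patient_nimg.sum())
    child_seeds = ss_images.spawn(n_images)

    images: list[SynthImage] = []
    annotations: list[AnnotationRecord] = []
    finals: list[FinalLabel] = []
    img_idx = 0
    for p in range(n_patients):
        patient_id = f"P{p + 1:05d}"
        site = sites[int(patient_site[p])]
        age = float(patient_age[p])
        for k in range(int(patient_nimg[p])):
            image_id = f"{patient_id}_{k + 1}"
            img_rng = np.random.default_rng(child_seeds[img_idx])
            img_idx += 1
            true_class = ClassLabel(int(img_rng.choice(N_CLASSES, p=priors[site])))
            image = synth_image(
                true_class,
                image_size,
                int(img_rng.integers(2**31)),
                image_id=image_id,
                patient_id=patient_id,
                site=site,
                age_months=age,
            )
            images.append(image)

            initial_recs = [
                AnnotationRecord(
                    image_id,
                    reader.reader_id,
                    sample_reader_label(reader, true_class, age, img_rng),
                    Phase.INITIAL,
                )
                for reader in site_readers[site]
            ]
            annotations.extend(initial_recs)
            final, extra = arbitrate(
                initial_recs, arbitrators, image, img_rng, qc_fraction=qc_fraction
            )
            annotations.extend(extra)
            finals.append(final)

    return PanelDataset(images, annotations, finals, profiles, seed)


def split_by_patient(
    images: Sequence[SynthImage], test_fraction: float, seed: int
) -> DatasetSplit:
    """Partition patients (not images) into train and test sets.

    Simple random sampling of patients, so every image of a patient lands on
    the same side of the split.  ``|test| = round(test_fraction * n)``.
    """
    if not 0 < test_fraction < 1:
        raise ValueError("test_fraction must be in (0, 1)")
    patients = sorted({im.patient_id for im in images})
    if len(patients) < 2:
        raise ValueError("need at least 2 patients to split")
    rng = np.random.default_rng(seed)
    n_test = int(round(test_fraction * len(patients)))
    n_test = min(max(n_test, 1), len(patients) - 1)
    test = set(rng.choice(patients, size=n_test, replace=False).tolist())
    train = set(patients) - test
    return DatasetSplit(frozenset(train), frozenset(test), seed)
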