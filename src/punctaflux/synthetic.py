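"""Ground-truth synthetic data: islet images, cohorts, density records, EM objects.

The image model is the standard fluorescence forward model: isotropic
Gaussian spots (diffraction-limited puncta) rendered inside an islet-shaped
region on a smooth background gradient, corrupted by Poisson shot noise
plus additive Gaussian read noise.  Colocalisation is planted by placing a
fraction *f* of child-channel spots on parent-spot centres (jitter <= 1 px);
the remaining children keep a 3-sigma exclusion distance from every parent
so accidental overlap does not inflate the planted fraction.  All
randomness flows through one seeded generator, so images are bit-identical
across runs with the same seed.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
from scipy import ndimage

from punctaflux.io_core import ChannelStack, SampleMeta

MAX_DENSITY = 0.2  # spots/px^2; beyond this spots are unresolvable

CHANNEL_ORDER = ("proinsulin", "lc3", "lamp1", "p62")


@dataclasses.dataclass
class Spot:
    row: float
    col: float
    sigma_px: float
    amplitude: float
    colocalized_with: int | None = None  # index of parent spot, if planted on one


@dataclasses.dataclass
class GroundTruth:
    """Everything planted in one synthetic image."""

    islet_mask: np.ndarray
    spots: dict[str, list[Spot]]
    coloc_fraction: dict[tuple[str, str], float]  # (child, parent) -> configured f
    seed: int

    def planted_fraction(self, child: str, parent: str) -> float:
        """Realised fraction of child spots planted on a parent centre."""
        kids = self.spots.get(child, [])
        if not kids:
            return float("nan")
        return sum(1 for s in kids if s.colocalized_with is not None) / len(kids)


@dataclasses.dataclass
class ArmConfig:
    """One cohort arm: a group x treatment cell and its generative parameters.

    Densities are spots per px^2 of islet area; ``coloc`` maps
    (child_role, parent_role) pairs to the planted overlap fraction f.
    """

    group: str
    treatment: str = "none"
    n_images: int = 20
    densities: dict[str, float] = dataclasses.field(
        default_factory=lambda: {"lc3": 0.0022, "lamp1": 0.0030, "p62": 0.0012, "proinsulin": 0.0022}
    )
    coloc: dict[tuple[str, str], float] = dataclasses.field(
        default_factory=lambda: {("lc3", "lamp1"): 0.6, ("proinsulin", "lamp1"): 0.5}
    )


@dataclasses.dataclass
class ImageConfig:
    """Rendering parameters shared across a cohort."""

    shape: tuple[int, int] = (192, 192)
    pixel_size_um: float = 0.1
    sigma_px: float = 1.2
    amplitude: float = 150.0
    amplitude_cv: float = 0.15
    background: float = 20.0
    gradient: float = 10.0
    read_noise: float = 3.0
    proinsulin_plate: float = 60.0  # base marker level filling the islet
    # Same-channel centre separation in units of sigma.  5 sigma keeps the
    # Otsu-thresholded footprints of neighbouring spots disjoint, matching the
    # no-declumping detection recipe; dense requests saturate below the
    # requested density rather than planting unresolvable spots.
    min_sep_sigma: float = 5.0


@dataclasses.dataclass
class CohortConfig:
    arms: list[ArmConfig]
    image: ImageConfig = dataclasses.field(default_factory=ImageConfig)
    seed: int = 1


def default_cohort_config(n_images: int = 8, seed: int = 1) -> CohortConfig:
    """Three disease groups x two treatments echoing the study design.

    The control-like arm has high autophagosome-lysosome overlap (f = 0.6)
    and doubles its LC3/p62 density under chloroquine; the pre-disease arm
    has slightly lower overlap with elevated baseline child density and an
    LC3 (not p62) chloroquine response; the disease arm has low overlap
    (f = 0.25) and no chloroquine-induced accumulation at all.
    """

    def arm(group, treatment, lc3, p62, f):
        return ArmConfig(
            group=group,
            treatment=treatment,
            n_images=n_images,
            densities={"lc3": lc3, "lamp1": 0.0030, "p62": p62, "proinsulin": 0.0022},
            coloc={("lc3", "lamp1"): f, ("proinsulin", "lamp1"): f},
        )

    arms = [
        arm("NOR", "none", 0.0020, 0.0010, 0.60),
        arm("NOR", "chloroquine", 0.0040, 0.0020, 0.30),
        arm("NOD_nondiabetic", "none", 0.0028, 0.0025, 0.55),
        arm("NOD_nondiabetic", "chloroquine", 0.0056, 0.0025, 0.28),
        arm("NOD_diabetic", "none", 0.0030, 0.0025, 0.25),
        arm("NOD_diabetic", "chloroquine", 0.0030, 0.0025, 0.15),
    ]
    return CohortConfig(arms=arms, seed=seed)


# ---------------------------------------------------------------- geometry


def _islet_mask(shape: tuple[int, int], rng: np.random.Generator) -> np.ndarray:
    """Smooth random blob occupying roughly the central third of the frame."""
    h, w = shape
    r0 = 0.32 * min(h, w)
    n_harm = 4
    amp = rng.uniform(0.03, 0.10, size=n_harm)
    phase = rng.uniform(0, 2 * np.pi, size=n_harm)
    cy = h / 2 + rng.uniform(-0.04, 0.04) * h
    cx = w / 2 + rng.uniform(-0.04, 0.04) * w
    yy, xx = np.mgrid[0:h, 0:w]
    theta = np.arctan2(yy - cy, xx - cx)
    radius = r0 * (
        1.0 + sum(a * np.sin((k + 2) * theta + p) for k, (a, p) in enumerate(zip(amp, phase)))
    )
    dist = np.hypot(yy - cy, xx - cx)
    return dist <= radius


class _SeparationGrid:
    """Uniform-grid index for min-distance rejection sampling (O(1)/query)."""

    def __init__(self, min_sep: float):
        self.min_sep = min_sep
        self.cells: dict[tuple[int, int], list[tuple[float, float]]] = {}

    def _cell(self, r: float, c: float) -> tuple[int, int]:
        return int(r // self.min_sep), int(c // self.min_sep)

    def ok(self, r: float, c: float) -> bool:
        ci, cj = self._cell(r, c)
        for di in (-1, 0, 1):
            for dj in (-1, 0, 1):
                for (pr, pc) in self.cells.get((ci + di, cj + dj), ()):
                    if (pr - r) ** 2 + (pc - c) ** 2 < self.min_sep**2:
                        return False
        return True

    def add(self, r: float, c: float) -> None:
        self.cells.setdefault(self._cell(r, c), []).append((r, c))


def _scatter_in_mask(
    n: int,
    mask: np.ndarray,
    min_sep: float,
    rng: np.random.Generator,
    avoid: _SeparationGrid | None = None,
) -> list[tuple[float, float]]:
    """Place up to ``n`` points uniformly in ``mask`` keeping ``min_sep`` apart.

    ``avoid`` adds an extra exclusion index (e.g. parent centres the
    non-colocalised children must stay away from).  Dense configurations
    may yield fewer than ``n`` points; the caller records what was planted.
    """
    rows, cols = np.nonzero(mask)
    if rows.size == 0 or n == 0:
        return []
    own = _SeparationGrid(min_sep)
    placed: list[tuple[float, float]] = []
    attempts = 0
    max_attempts = 400 * n
    while len(placed) < n and attempts < max_attempts:
        attempts += 1
        k = rng.integers(0, rows.size)
        r = rows[k] + rng.uniform(-0.5, 0.5)
        c = cols[k] + rng.uniform(-0.5, 0.5)
        if not own.ok(r, c):
            continue
        if avoid is not None and not avoid.ok(r, c):
            continue
        own.add(r, c)
        placed.append((float(r), float(c)))
    return placed


# ---------------------------------------------------------------- rendering


def _render_spots(canvas: np.ndarray, spots: list[Spot]) -> None:
    h, w = canvas.shape
    for s in spots:
        rad = int(np.ceil(4 * s.sigma_px))
        r0, r1 = max(0, int(s.row) - rad), min(h, int(s.row) + rad + 1)
        c0, c1 = max(0, int(s.col) - rad), min(w, int(s.col) + rad + 1)
        if r0 >= r1 or c0 >= c1:
            continue
        yy = np.arange(r0, r1)[:, None] - s.row
        xx = np.arange(c0, c1)[None, :] - s.col
        canvas[r0:r1, c0:c1] += s.amplitude * np.exp(-(yy**2 + xx**2) / (2 * s.sigma_px**2))


def _noisy(clean: np.ndarray, read_noise: float, rng: np.random.Generator) -> np.ndarray:
    shot = rng.poisson(np.clip(clean, 0, None)).astype(np.float64)
    out = shot + rng.normal(0.0, read_noise, size=clean.shape)
    return np.clip(out, 0.0, None)


def generate_islet_image(
    arm: ArmConfig,
    seed: int,
    image: ImageConfig | None = None,
    image_id: str = "",
) -> tuple[ChannelStack, GroundTruth]:
    """Render one multichannel islet field with known ground truth.

    Channels rendered: granular proinsulin (plate + puncta), LC3, LAMP1 and
    p62 puncta, each with its configured density inside the islet; child
    spots of each configured (child, parent) pair are planted on parent
    centres with probability f.  Densities above 0.2 spots/px^2 are
    rejected as unresolvable.
    """
    image = image or ImageConfig()
    for role, dens in arm.densities.items():
        if dens < 0:
            raise ValueError(f"negative density for {role!r}")
        if dens > MAX_DENSITY:
            raise ValueError(f"density {dens}/px^2 for {role!r} exceeds resolvable {MAX_DENSITY}")
    rng = np.random.default_rng(seed)
    mask = _islet_mask(image.shape, rng)
    area = int(mask.sum())
    min_sep = image.min_sep_sigma * image.sigma_px

    parents_by_role: dict[str, tuple[list[tuple[float, float]], _SeparationGrid]] = {}
    spots: dict[str, list[Spot]] = {}

    def amplitude() -> float:
        return float(image.amplitude * max(0.2, 1.0 + image.amplitude_cv * rng.normal()))

    child_of = {c: p for (c, p) in arm.coloc}

    # Parent channels (anything that is not a child in a coloc pair) first.
    order = [r for r in CHANNEL_ORDER if r in arm.densities]
    for role in sorted(order, key=lambda r: r in child_of):
        n = int(rng.poisson(arm.densities[role] * area))
        parent_role = child_of.get(role)
        if parent_role is None:
            centres = _scatter_in_mask(n, mask, min_sep, rng)
            grid = _SeparationGrid(min_sep)
            for r, c in centres:
                grid.add(r, c)
            parents_by_role[role] = (centres, grid)
            spots[role] = [Spot(r, c, image.sigma_px, amplitude()) for r, c in centres]
        else:
            f = arm.coloc[(role, parent_role)]
            if not 0.0 <= f <= 1.0:
                raise ValueError(f"coloc fraction must be in [0,1], got {f}")
            parent_centres, parent_grid = parents_by_role[parent_role]
            n_coloc = int(rng.binomial(n, f)) if n else 0
            n_coloc = min(n_coloc, len(parent_centres))
            chosen = rng.choice(len(parent_centres), size=n_coloc, replace=False) if n_coloc else []
            role_spots: list[Spot] = []
            for idx in chosen:
                pr, pc = parent_centres[idx]
                ang = rng.uniform(0, 2 * np.pi)
                rad = rng.uniform(0, 1.0)  # jitter within 1 px of the parent centre
                role_spots.append(
                    Spot(pr + rad * np.sin(ang), pc + rad * np.cos(ang), image.sigma_px,
                         amplitude(), colocalized_with=int(idx))
                )
            free = _scatter_in_mask(n - n_coloc, mask, min_sep, rng, avoid=parent_grid)
            role_spots.extend(Spot(r, c, image.sigma_px, amplitude()) for r, c in free)
            spots[role] = role_spots

    h, w = image.shape
    yy, xx = np.mgrid[0:h, 0:w]
    channels: dict[str, np.ndarray] = {}
    for role in order:
        gdir = rng.uniform(0, 2 * np.pi)
        plane = image.background + image.gradient * (
            (xx * np.cos(gdir) + yy * np.sin(gdir)) / max(h, w)
        )
        clean = np.clip(plane, 0, None)
        if role == "proinsulin":
            texture = ndimage.gaussian_filter(rng.normal(0, 1, size=(h, w)), 2.0)
            clean = clean + mask * (image.proinsulin_plate * (1 + 0.15 * texture))
        canvas = np.zeros((h, w))
        _render_spots(canvas, spots[role])
        clean = clean + canvas
        channels[role] = _noisy(clean, image.read_noise, rng)

    stack = ChannelStack(channels=channels, pixel_size_um=image.pixel_size_um,
                         image_id=image_id or f"synth_{seed}")
    truth = GroundTruth(islet_mask=mask, spots=spots, coloc_fraction=dict(arm.coloc), seed=seed)
    return stack, truth


def generate_cohort(cfg: CohortConfig):
    """Generate every arm of a cohort.

    Yields ``(ChannelStack, GroundTruth, SampleMeta)`` triples; image seeds
    are drawn deterministically from ``cfg.seed``.
    """
    master = np.random.default_rng(cfg.seed)
    for arm in cfg.arms:
        for i in range(arm.n_images):
            sub_seed = int(master.integers(0, 2**31 - 1))
            image_id = f"{arm.group}_{arm.treatment}_{i:03d}"
            stack, truth = generate_islet_image(arm, sub_seed, image=cfg.image, image_id=image_id)
            meta = SampleMeta(group=arm.group, treatment=arm.treatment,
                              subject_id=f"{arm.group}_s{i % 5}")
            yield stack, truth, meta


def ground_truth_table(cohort) -> pd.DataFrame:
    """Planted per-image summary: spot counts and realised coloc fractions."""
    rows = []
    for stack, truth, meta in cohort:
        row = {
            "image_id": stack.image_id,
            "group": meta.group,
            "treatment": meta.treatment,
            "islet_area_px": int(truth.islet_mask.sum()),
            "seed": truth.seed,
        }
        for role, ss in truth.spots.items():
            row[f"n_{role}"] = len(ss)
        for (child, parent), f in truth.coloc_fraction.items():
            row[f"f_cfg_{child}_in_{parent}"] = f
            row[f"f_real_{child}_in_{parent}"] = truth.planted_fraction(child, parent)
        rows.append(row)
    return pd.DataFrame(rows)


def write_cohort(cfg: CohortConfig, out_dir: str | Path) -> pd.DataFrame:
    """Write a cohort to disk: multipage TIFFs, islet masks, manifest, truth table.

    Channel page order in each TIFF follows ``CHANNEL_ORDER``.  Returns the
    manifest frame (one row per image) that the ``quantify`` command consumes.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest_rows, triples = [], []
    for stack, truth, meta in generate_cohort(cfg):
        roles = [r for r in CHANNEL_ORDER if r in stack.channels]
        pages = np.stack([stack[r] for r in roles]).astype(np.float32)
        img_path = out_dir / f"{stack.image_id}.tif"
        mask_path = out_dir / f"{stack.image_id}_mask.tif"
        tifffile.imwrite(img_path, pages, photometric='minisblack')
        tifffile.imwrite(mask_path, truth.islet_mask.astype(np.uint8) * 255)
        manifest_rows.append(
            {
                "image_path": str(img_path),
                "mask_path": str(mask_path),
                "pixel_size_um": stack.pixel_size_um,
                "group": meta.group,
                "treatment": meta.treatment,
                "subject_id": meta.subject_id,
                "channel_map": ";".join(f"{r}:{i}" for i, r in enumerate(roles)),
            }
        )
        triples.append((stack, truth, meta))
    manifest = pd.DataFrame(manifest_rows)
    manifest.to_csv(out_dir / "manifest.csv", index=False)
    ground_truth_table(triples).to_csv(out_dir / "ground_truth.csv", index=False)
    return manifest


# ------------------------------------------------------- record-level cohorts


def sample_density_records(
    arm_means: dict[tuple[str, str], float],
    n_per_arm: int,
    rng: np.random.Generator | int,
    value: str = "density_lc3_per_um2",
    cv: float = 0.25,
) -> pd.DataFrame:
    """Sample per-islet density records straight from arm-level means.

    Each (group, treatment) arm contributes ``n_per_arm`` islets whose
    densities follow a gamma distribution with the given mean and
    coefficient of variation — a standard positive-valued noise model for
    count densities.  This is the fast harness for the flux/fold-change
    decision logic; image-level generation exercises the detection path.
    """
    rng = np.random.default_rng(rng) if isinstance(rng, (int, np.integer)) else rng
    if cv <= 0:
        raise ValueError("cv must be positive")
    shape = 1.0 / cv**2
    rows = []
    for (group, treatment), mean in arm_means.items():
        if mean < 0:
            raise ValueError("arm means must be non-negative")
        if mean == 0:
            vals = np.zeros(n_per_arm)
        else:
            vals = rng.gamma(shape, mean / shape, size=n_per_arm)
        for i, v in enumerate(vals):
            rows.append(
                {"group": group, "treatment": treatment, "subject_id": f"{group}_s{i % 5}",
                 value: float(v)}
            )
    return pd.DataFrame(rows)


# ------------------------------------------------------------- EM synthesis


def generate_em_object(
    ringed: bool,
    rng: np.random.Generator,
    radius_px: int = 12,
    canvas: int = 40,
    shell_width: int = 3,
    n_level: float = 100.0,
    noise: float = 8.0,
):
    """One synthetic lysosomal object: disc mask plus N and P elemental maps.

    Ringed objects carry their nitrogen in a peripheral shell of
    ``shell_width`` pixels over a dim core; un-ringed objects spread the
    same nitrogen uniformly.  Phosphorus is core-enriched in both, matching
    a phospholipid-rich interior.
    """
    c = canvas // 2
    yy, xx = np.mgrid[0:canvas, 0:canvas]
    dist = np.hypot(yy - c, xx - c)
    mask = dist <= radius_px
    shell = mask & (dist > radius_px - shell_width)
    core = mask & ~shell
    n_map = rng.normal(10.0, noise, size=(canvas, canvas))
    if ringed:
        n_map[shell] += n_level
        n_map[core] += 0.25 * n_level
    else:
        n_map[mask] += 0.6 * n_level
    p_map = rng.normal(10.0, noise, size=(canvas, canvas))
    p_map[core] += 80.0
    return mask, np.clip(n_map, 0, None), np.clip(p_map, 0, None)


def generate_em_cohort(
    n_objects: int,
    ring_fraction: float,
    seed: int,
    telo_fraction: float = 0.5,
) -> list[dict]:
    """A set of annotated synthetic lysosomes with planted ring ground truth."""
    rng = np.random.default_rng(seed)
    out = []
    n_ringed = int(round(ring_fraction * n_objects))
    ringed_flags = np.zeros(n_objects, dtype=bool)
    ringed_flags[:n_ringed] = True
    rng.shuffle(ringed_flags)
    for i, ringed in enumerate(ringed_flags):
        kind = "telolysosome" if rng.uniform() < telo_fraction else "secondary"
        mask, n_map, p_map = generate_em_object(bool(ringed), rng,
                                                radius_px=int(rng.integers(10, 15)))
        out.append(
            {"object_id": i + 1, "kind": kind, "ringed": bool(ringed),
             "mask": mask, "n_map": n_map, "p_map": p_map}
        )
    return out
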