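"""Ground-truth evaluation harnesses for the synthetic study conditions.

Each function regenerates synthetic data with known ground truth, runs the
real pipeline on it, and measures recovery: detection precision/recall,
colocalisation bias, flux-call reproduction, statistical calibration, ring
recovery, and end-to-end determinism.  Both the test suite and the
reproduction script drive these; they contain no expected values.
"""

from __future__ import annotations

import hashlib
from pathlib import Path

import numpy as np
import pandas as pd

from punctaflux.colocalize import percent_colocalized
from punctaflux.em_rings import occupancy, rim_classify
from punctaflux.io_core import SampleMeta
from punctaflux.pipeline import quantify_stack, run_quantify
from punctaflux.preprocess import subtract_lower_quartile
from punctaflux.puncta import detect_puncta
from punctaflux.roi import ROIMask
from punctaflux.stats_flux import assess_flux, one_way_anova_tukey
from punctaflux.synthetic import (
    ArmConfig,
    CohortConfig,
    default_cohort_config,
    generate_em_cohort,
    generate_islet_image,
    sample_density_records,
    write_cohort,
)


def _spawn(seed: int, n: int) -> list[int]:
    rng = np.random.default_rng(seed)
    return [int(s) for s in rng.integers(0, 2**31 - 1, size=n)]


def match_detections(
    planted: np.ndarray, detected: np.ndarray, tol_px: float = 2.0
) -> int:
    """Greedy one-to-one matching of detected centroids to planted centres."""
    if len(planted) == 0 or len(detected) == 0:
        return 0
    dists = np.linalg.norm(planted[None, :, :] - detected[:, None, :], axis=2)
    nearest = dists.min(axis=1)
    order = np.argsort(nearest)
    matched: set[int] = set()
    tp = 0
    for k in order:
        if nearest[k] > tol_px:
            break
        j = int(dists[k].argmin())
        while j in matched:
            dists[k, j] = np.inf
            j = int(dists[k].argmin())
            if not np.isfinite(dists[k, j]):
                j = -1
                break
        if j >= 0 and dists[k, j] <= tol_px:
            matched.add(j)
            tp += 1
    return tp


def detection_precision_recall(
    density: float, seed: int, n_images: int = 5, tol_px: float = 2.0
) -> tuple[float, float]:
    """Pooled precision/recall of puncta detection against planted spots."""
    tp = n_det = n_planted = 0
    for s in _spawn(seed, n_images):
        arm = ArmConfig(group="NOR", densities={"lc3": density}, coloc={})
        stack, truth = generate_islet_image(arm, s)
        roi = ROIMask(truth.islet_mask, mode="manual")
        ps = detect_puncta(subtract_lower_quartile(stack["lc3"]), roi, channel_role="lc3")
        planted = np.array([(sp.row, sp.col) for sp in truth.spots["lc3"]])
        detected = np.array([p.centroid for p in ps.objects]).reshape(-1, 2)
        tp += match_detections(planted, detected, tol_px)
        n_det += len(detected)
        n_planted += len(planted)
    return tp / max(n_det, 1), tp / max(n_planted, 1)


def coloc_recovery(f: float, seed: int, n_images: int = 20) -> float:
    """Mean estimated percent colocalised over a planted-f cohort."""
    estimates = []
    for s in _spawn(seed, n_images):
        arm = ArmConfig(
            group="NOR",
            coloc={("lc3", "lamp1"): f},
            densities={"lc3": 0.0022, "lamp1": 0.0030},
        )
        stack, truth = generate_islet_image(arm, s)
        roi = ROIMask(truth.islet_mask, mode="manual")
        lc3 = detect_puncta(subtract_lower_quartile(stack["lc3"]), roi, channel_role="lc3")
        lamp1 = detect_puncta(subtract_lower_quartile(stack["lamp1"]), roi, channel_role="lamp1")
        res = percent_colocalized(lc3, lamp1)
        if not res.flag_zero_children:
            estimates.append(res.percent)
    return float(np.mean(estimates))


def density_linearity_r2(seed: int, n_images: int = 4) -> float:
    """R^2 of estimated vs planted density over a 5-point density ladder."""
    ladder = [0.001, 0.002, 0.004, 0.008, 0.016]
    planted, estimated = [], []
    for i, dens in enumerate(ladder):
        for s in _spawn(seed + i, n_images):
            arm = ArmConfig(group="NOR", densities={"lc3": dens}, coloc={})
            stack, truth = generate_islet_image(arm, s)
            roi = ROIMask(truth.islet_mask, mode="manual")
            ps = detect_puncta(subtract_lower_quartile(stack["lc3"]), roi, channel_role="lc3")
            planted.append(len(truth.spots["lc3"]) / truth.islet_mask.sum())
            estimated.append(ps.count / roi.area_px)
    slope, intercept = np.polyfit(planted, estimated, 1)
    fit = slope * np.asarray(planted) + intercept
    resid = np.asarray(estimated) - fit
    ss_tot = ((np.asarray(estimated) - np.mean(estimated)) ** 2).sum()
    return float(1.0 - (resid**2).sum() / ss_tot)


LC3_FLUX_SCENARIO = {
    ("A", "none"): 1.0,
    ("A", "chloroquine"): 2.0,  # chloroquine doubles LC3 density: flux intact
    ("B", "none"): 1.0,
    ("B", "chloroquine"): 1.0,  # no accumulation: flux impaired
}

P62_SCENARIO = {
    ("NOR", "none"): 0.5,
    ("NOR", "chloroquine"): 1.0,  # p62 rises under blockade only here
    ("NOD_nondiabetic", "none"): 1.25,  # elevated already at baseline
    ("NOD_nondiabetic", "chloroquine"): 1.25,
    ("NOD_diabetic", "none"): 1.25,
    ("NOD_diabetic", "chloroquine"): 1.25,
}


def flux_call_accuracy(seed: int, n_runs: int = 100, n_per_arm: int = 15) -> float:
    """Fraction of re-seeded runs calling the doubling arm intact, flat arm impaired."""
    correct = 0
    for s in _spawn(seed, n_runs):
        rec = sample_density_records(LC3_FLUX_SCENARIO, n_per_arm, s)
        calls = {c.group: c.call for c in assess_flux(rec, "density_lc3_per_um2")}
        if calls == {"A": "intact", "B": "impaired"}:
            correct += 1
    return correct / n_runs


def p62_pattern(seed: int, n_per_arm: int = 20) -> dict:
    """Reproduce the p62 pattern: baseline elevation in disease-model arms,
    chloroquine-induced increase only in the control arm."""
    rec = sample_density_records(P62_SCENARIO, n_per_arm, seed, value="density_p62_per_um2")
    baseline = rec[rec.treatment == "none"]
    tukey = one_way_anova_tukey(baseline, "density_p62_per_um2", "group")
    elevated = {}
    for _, row in tukey.contrasts.iterrows():
        if "NOR" in row["contrast"]:
            other = row["contrast"].replace("NOR", "").replace(" - ", "").strip()
            elevated[other] = bool(row["p_adj"] < 0.05 and abs(row["estimate"]) > 0)
    calls = {c.group: c.call for c in assess_flux(rec, "density_p62_per_um2")}
    return {"baseline_elevated": elevated, "flux_calls": calls}


def type1_error_rate(seed: int, n_reps: int = 1000, n_per_group: int = 30) -> float:
    """Null rejection rate of the one-way omnibus test at alpha = 0.05."""
    rng = np.random.default_rng(seed)
    rejections = 0
    for _ in range(n_reps):
        frame = pd.DataFrame(
            {
                "group": np.repeat(list("abc"), n_per_group),
                "y": rng.normal(0, 1, 3 * n_per_group),
            }
        )
        table = one_way_anova_tukey(frame, "y", "group", posthoc=False)
        if table.omnibus.set_index("term").loc["group", "p"] < 0.05:
            rejections += 1
    return rejections / n_reps


def ring_recovery(seed: int, planted_fraction: float = 0.70, n_objects: int = 100) -> dict:
    """Recovered rim-positive percentage on a planted-ring object cohort."""
    cohort = generate_em_cohort(n_objects, planted_fraction, seed)
    results = [
        rim_classify(o["mask"], o["n_map"], o["p_map"], kind=o["kind"], object_id=o["object_id"])
        for o in cohort
    ]
    table = occupancy(results)
    return {
        "percent_positive": 100.0 * float(np.mean([r.rim_positive for r in results])),
        "occupancy_sum": float(table["percent"].sum()),
    }


def determinism_check(work_dir: str | Path, seed: int, n_images: int = 2) -> bool:
    """Two identical synth+quantify runs produce byte-identical islets.csv."""
    work_dir = Path(work_dir)
    digests = []
    for run in ("a", "b"):
        data = work_dir / f"data_{run}"
        out = work_dir / f"out_{run}"
        write_cohort(default_cohort_config(n_images=n_images, seed=seed), data)
        run_quantify(data / "manifest.csv", out)
        digests.append(hashlib.sha256((out / "islets.csv").read_bytes()).hexdigest())
    return digests[0] == digests[1]


def cohort_group_means(seed: int, n_images: int = 8) -> dict[str, float]:
    """Group-mean LC3-in-LAMP1 percent over the untreated arms of the
    default cohort, computed by the full image pipeline with manual ROIs."""
    cfg = default_cohort_config(n_images=n_images, seed=seed)
    cfg.arms = [a for a in cfg.arms if a.treatment == "none"]
    rng = np.random.default_rng(seed)
    means: dict[str, float] = {}
    for arm in cfg.arms:
        vals = []
        for _ in range(arm.n_images):
            stack, truth = generate_islet_image(arm, int(rng.integers(2**31 - 1)))
            rec = quantify_stack(
                stack,
                SampleMeta(group=arm.group, treatment=arm.treatment),
                mask=ROIMask(truth.islet_mask, mode="manual"),
            )
            if np.isfinite(rec.pct_lc3_in_lamp1):
                vals.append(rec.pct_lc3_in_lamp1)
        means[arm.group] = float(np.mean(vals))
    return means
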