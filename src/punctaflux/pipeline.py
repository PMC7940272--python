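"""End-to-end orchestration: manifest -> per-islet table -> statistics.

The run configuration is a nested dict (YAML-friendly) with defaults in
:data:`DEFAULT_CONFIG`; every run writes its resolved configuration and a
QC log beside the outputs so results are reproducible from the artefacts
alone.
"""

from __future__ import annotations

import copy
import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd

from punctaflux import __version__
from punctaflux.colocalize import percent_colocalized
from punctaflux.io_core import (
    ChannelStack,
    IsletRecord,
    SampleMeta,
    load_mask,
    load_stack,
    records_to_frame,
    write_islet_table,
)
from punctaflux.preprocess import subtract_lower_quartile
from punctaflux.puncta import detect_puncta, puncta_density
from punctaflux.roi import ROIMask, segment_marker_roi
from punctaflux.stats_flux import (
    assess_flux,
    group_summary,
    one_way_anova_tukey,
    two_way_anova_sidak,
)

PUNCTA_ROLES = ("lc3", "lamp1", "p62", "proinsulin")

DEFAULT_CONFIG: dict = {
    "background": {"quantile": 0.25},
    "median": {"radius": 1},
    "roi": {"mode": "marker", "marker": "proinsulin", "min_area_px": 100, "close_radius": 2},
    "puncta": {
        role: {"d_min": 2.0, "d_max": 10.0, "median_radius": 1, "threshold": None}
        for role in PUNCTA_ROLES
    },
    "coloc": {"min_overlap_frac": 0.0},
    "alpha": 0.05,
}


def resolve_config(overrides: dict | None = None) -> dict:
    cfg = copy.deepcopy(DEFAULT_CONFIG)

    def merge(dst, src):
        for k, v in src.items():
            if isinstance(v, dict) and isinstance(dst.get(k), dict):
                merge(dst[k], v)
            else:
                dst[k] = v

    if overrides:
        merge(cfg, overrides)
    return cfg


def quantify_stack(
    stack: ChannelStack,
    meta: SampleMeta,
    mask: ROIMask | None = None,
    config: dict | None = None,
) -> IsletRecord:
    """Quantify one islet image into a single record.

    Steps: lower-quartile background subtraction per channel; ROI from the
    configured marker channel (or the supplied manual mask); per-channel
    puncta detection with the diameter gate; densities normalised to ROI
    area; LC3-in-LAMP1 and proinsulin-in-LAMP1 object-overlap percentages.
    """
    cfg = resolve_config(config)
    clean = {
        role: subtract_lower_quartile(stack[role], quantile=cfg["background"]["quantile"])
        for role in PUNCTA_ROLES
        if role in stack
    }

    if mask is not None:
        roi = mask
    else:
        marker_role = cfg["roi"]["marker"]
        if marker_role not in clean:
            raise ValueError(f"marker channel {marker_role!r} absent and no manual mask given")
        roi = segment_marker_roi(
            clean[marker_role],
            min_area_px=cfg["roi"]["min_area_px"],
            close_radius=cfg["roi"]["close_radius"],
        )

    record = IsletRecord(
        image_id=stack.image_id,
        subject_id=meta.subject_id,
        group=meta.group,
        treatment=meta.treatment,
        roi_area_px=roi.area_px,
        roi_area_um2=roi.area_um2(stack.pixel_size_um),
        flag_empty_roi=roi.is_empty,
    )
    if roi.is_empty:
        return record

    puncta = {}
    for role, chan in clean.items():
        pcfg = cfg["puncta"][role]
        puncta[role] = detect_puncta(
            chan,
            roi,
            d_min=pcfg["d_min"],
            d_max=pcfg["d_max"],
            median_radius=pcfg["median_radius"],
            threshold=pcfg["threshold"],
            channel_role=role,
        )
        dens = puncta_density(puncta[role], roi, stack.pixel_size_um)
        setattr(record, f"density_{role}_per_um2", dens["per_um2"])

    frac = cfg["coloc"]["min_overlap_frac"]
    if "lc3" in puncta and "lamp1" in puncta:
        res = percent_colocalized(puncta["lc3"], puncta["lamp1"], min_overlap_frac=frac)
        record.pct_lc3_in_lamp1 = res.percent
        record.flag_zero_children = record.flag_zero_children or res.flag_zero_children
    if "proinsulin" in puncta and "lamp1" in puncta:
        res = percent_colocalized(puncta["proinsulin"], puncta["lamp1"], min_overlap_frac=frac)
        record.pct_proins_in_lamp1 = res.percent
        record.flag_zero_children = record.flag_zero_children or res.flag_zero_children
    return record


def _parse_channel_map(text: str) -> dict[str, int]:
    out = {}
    for part in str(text).split(";"):
        role, idx = part.split(":")
        out[role.strip()] = int(idx)
    return out


def run_quantify(
    manifest: pd.DataFrame | str | Path,
    out_dir: str | Path,
    config: dict | None = None,
) -> pd.DataFrame:
    """Quantify every image of a manifest and write ``islets.csv`` + run log.

    The manifest needs columns ``image_path``, ``pixel_size_um``, ``group``,
    ``treatment``, ``subject_id``, ``channel_map`` (``role:index`` pairs
    joined by ``;``) and optionally ``mask_path``.  Any unreadable input
    aborts with the offending path named.
    """
    if not isinstance(manifest, pd.DataFrame):
        manifest_path = Path(manifest)
        if not manifest_path.is_file():
            raise FileNotFoundError(f"manifest not found: {manifest_path}")
        manifest = pd.read_csv(manifest_path)
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    cfg = resolve_config(config)

    records, qc = [], []
    for _, row in manifest.iterrows():
        stack = load_stack(row["image_path"], _parse_channel_map(row["channel_map"]),
                           row["pixel_size_um"])
        mask = None
        if "mask_path" in row and isinstance(row["mask_path"], str) and row["mask_path"]:
            mask = load_mask(row["mask_path"])
        meta = SampleMeta(group=row["group"], treatment=row["treatment"],
                          subject_id=str(row["subject_id"]))
        rec = quantify_stack(stack, meta, mask=mask, config=cfg)
        records.append(rec)
        if rec.flag_empty_roi or rec.flag_zero_children:
            qc.append(
                {"image_id": rec.image_id, "empty_roi": rec.flag_empty_roi,
                 "zero_children": rec.flag_zero_children}
            )

    frame = records_to_frame(records)
    write_islet_table(frame, out_dir / "islets.csv")
    cfg_json = json.dumps(cfg, sort_keys=True, default=str)
    log = {
        "version": __version__,
        "config": cfg,
        "config_sha256": hashlib.sha256(cfg_json.encode()).hexdigest(),
        "n_images": int(len(manifest)),
        "qc_flags": qc,
    }
    (out_dir / "run.log").write_text(json.dumps(log, indent=2, default=str) + "\n")
    return frame


def run_report(
    islets: pd.DataFrame | str | Path,
    out_dir: str | Path,
    design: str = "group*treatment",
    metrics: list[str] | None = None,
    alpha: float = 0.05,
) -> dict[str, pd.DataFrame]:
    """Group-comparison tables, flux calls and mean +/- SEM summaries.

    ``design`` is either ``"group"`` (one-way ANOVA, Tukey) or
    ``"group*treatment"`` (two-way ANOVA, Sidak within-group contrasts plus
    flux calls on every density metric).
    """
    if not isinstance(islets, pd.DataFrame):
        from punctaflux.io_core import read_islet_table

        islets = read_islet_table(islets)
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    if design not in ("group", "group*treatment"):
        raise ValueError(f"unknown design {design!r}")

    if metrics is None:
        metrics = [
            c
            for c in islets.columns
            if c.startswith("density_") or c.startswith("pct_")
        ]
    usable = islets.loc[~islets.get("flag_empty_roi", False).astype(bool)]

    comparisons, flux_rows, summaries = [], [], []
    factors = ["group"] if design == "group" else ["group", "treatment"]
    for metric in metrics:
        data = usable.dropna(subset=[metric])
        if data["group"].nunique() < 2:
            raise ValueError("design needs at least two group levels")
        summaries.append(group_summary(data, metric, factors).assign(metric=metric))
        try:
            if design == "group":
                table = one_way_anova_tukey(data, metric, "group", alpha=alpha)
            else:
                table = two_way_anova_sidak(data, metric)
        except ValueError:
            continue  # metric not estimable under this design (e.g. single arm)
        comparisons.append(table.contrasts.assign(metric=metric))
        if design == "group*treatment" and metric.startswith("density_"):
            try:
                calls = assess_flux(data, metric, alpha=alpha)
            except ValueError:
                continue
            flux_rows.extend(
                {
                    "metric": metric,
                    "group": c.group,
                    "delta_puncta": c.delta_puncta,
                    "p_adjusted": c.p_adjusted,
                    "call": c.call,
                }
                for c in calls
            )

    out = {
        "comparisons": pd.concat(comparisons, ignore_index=True) if comparisons else pd.DataFrame(),
        "summary": pd.concat(summaries, ignore_index=True),
        "flux_calls": pd.DataFrame(flux_rows),
    }
    out["comparisons"].to_csv(out_dir / "comparisons.csv", index=False)
    out["summary"].to_csv(out_dir / "summary.csv", index=False)
    out["flux_calls"].to_csv(out_dir / "flux_calls.csv", index=False)
    return out
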