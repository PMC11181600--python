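"""Pipeline orchestration: simulate → eCAPs → physio → DRC → dosing → report.

``run_all`` chains every stage deterministically from one seed and returns
a report bundle (thresholds table, alignment table, dose map with
feasibility mask and constrained optimum, latent space when enough
stimulation locations exist, and per-stage notes with parameter
provenance). ``render_report`` turns a bundle into a byte-stable
human-readable summary.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from . import dosing, drcmodels, ecaps, physio, synth
from .errors import ConfigurationError, ValidationError
from .session import Session, read_session, write_session

log = logging.getLogger("ecapkit.pipeline")

PRESETS = ("default", "recruitment", "latent")


def preset_config(name: str) -> synth.SessionConfig:
    if name == "default":
        return synth.SessionConfig()
    if name == "recruitment":
        return synth.recruitment_grid()
    if name == "latent":
        return synth.latent_grid()
    raise ConfigurationError(
        f"unknown preset {name!r}; expected one of {PRESETS}")


@dataclass(frozen=True)
class PipelineConfig:
    """One-shot pipeline configuration."""

    seed: int = 0
    preset: str = "default"
    session_path: str | None = None  # read instead of simulating
    channel_id: str = "cuffA"
    fibers: tuple[str, ...] = ("Abeta", "Agamma", "Adelta", "B")
    constraints: tuple[dosing.Constraint, ...] = (
        dosing.Constraint("delta_br_pct", "ge", -60.0),
        dosing.Constraint("twitch_count", "le", 100.0),
    )
    objective: str = "min"  # bradycardia target: minimise ΔHR
    grid_n: int = 21

    def validate(self) -> None:
        if self.session_path is None:
            preset_config(self.preset)  # raises on unknown preset
        if self.objective not in ("min", "max"):
            raise ConfigurationError("objective must be 'min' or 'max'")

    def digest(self) -> str:
        payload = {k: (list(v) if isinstance(v, tuple) else v)
                   for k, v in asdict(self).items()}
        return hashlib.sha256(
            json.dumps(payload, sort_keys=True, default=str).encode()
        ).hexdigest()[:16]


@dataclass
class ReportBundle:
    """Everything ``run_all`` produces, traceable to stage outputs."""

    config: PipelineConfig
    session: Session
    activations: pd.DataFrame
    physio: pd.DataFrame
    thresholds: pd.DataFrame
    alignment: pd.DataFrame
    dose_map: dosing.DoseMap | None
    optimum: tuple | None
    latent: dosing.LatentSpace | None
    notes: list[str] = field(default_factory=list)


# ---------------------------------------------------------------------------
# DRC / alignment stage
# ---------------------------------------------------------------------------

def fiber_thresholds_table(table: pd.DataFrame, fibers: Sequence[str],
                           channel_id: str) -> pd.DataFrame:
    """Neural thresholds per (fiber, contact pair, polarity, pulse width)."""
    rows = []
    sel = table[table["channel_id"] == channel_id]
    keys = ["fiber", "contact_pair", "polarity", "pulse_width_us"]
    for (fiber, pair, pol, pw), grp in sel.groupby(keys):
        if fiber not in fibers or grp["current_mA"].nunique() < 2:
            continue
        drc = ecaps.build_drc(table, fiber, pair, pol, pw,
                              channel_id=channel_id)
        cur, val = drcmodels.outlier_filter_post_max(
            drc.currents, drc.activations / drc.norm_ref)
        thr = drcmodels.neural_threshold(cur, val, norm_ref=1.0)
        rows.append({
            "fiber": fiber, "contact_pair": pair, "polarity": pol,
            "pulse_width_us": pw,
            "onset_mA": thr.onset_current,
            "saturation_mA": thr.saturation_current,
            "nominal": thr.nominal,
            "left_censored": thr.left_censored,
            "max_tested_mA": float(drc.currents.max()),
        })
    return pd.DataFrame(rows)


PHYSIO_EFFECT_COLUMNS = {
    # effect name -> (source column, transform to a non-negative magnitude)
    "bradycardia": ("delta_hr_bpm", lambda v: np.maximum(0.0, -v)),
    "bradypnea": ("delta_br_pct", lambda v: np.maximum(0.0, -v)),
    "twitch": ("twitch_amp_mean", lambda v: np.maximum(0.0, v)),
}


def physio_drc_values(physio_df: pd.DataFrame, effect: str,
                      ) -> tuple[np.ndarray, np.ndarray]:
    """Magnitude-vs-current DRC of one physiological effect.

    ΔHR and ΔBR are rectified to their bradycardia/bradypnea magnitudes so
    the onset of the *adverse-direction* effect defines the threshold (a
    low-current tachycardia bump must not set the bradycardia onset).
    Replicates at a current are averaged.
    """
    col, transform = PHYSIO_EFFECT_COLUMNS[effect]
    grp = physio_df.groupby("current_mA")[col].mean().sort_index()
    return grp.index.to_numpy(), transform(grp.to_numpy())


def alignment_table(table: pd.DataFrame, physio_df: pd.DataFrame,
                    fibers: Sequence[str], channel_id: str,
                    ) -> pd.DataFrame:
    """DRC alignment of every (fiber, physiological effect) pair.

    Physiological DRCs are taken at the frequency × duration subset with
    the strongest integration (highest frequency, then duration); neural
    thresholds use the matching pulse parameters.
    """
    sub = physio_df[
        (physio_df["frequency_hz"] == physio_df["frequency_hz"].max())]
    sub = sub[sub["duration_s"] == sub["duration_s"].max()]
    pair = sub["contact_pair"].iloc[0]
    pol = sub["polarity"].iloc[0]
    pw = sub["pulse_width_us"].iloc[0]
    tol = drcmodels.default_alignment_tolerance(
        sub["current_mA"].to_numpy())
    rows = []
    for fiber in fibers:
        try:
            drc = ecaps.build_drc(table, fiber, pair, pol, pw,
                                  channel_id=channel_id)
        except ValidationError:
            continue
        ncur, nval = drcmodels.outlier_filter_post_max(
            drc.currents, drc.activations / drc.norm_ref)
        n_thr = drcmodels.neural_threshold(ncur, nval, norm_ref=1.0)
        for effect in PHYSIO_EFFECT_COLUMNS:
            cur, val = physio_drc_values(sub, effect)
            if val.max() <= 0:
                continue
            p_thr = drcmodels.neural_threshold(cur, val)
            rep = drcmodels.drc_alignment(n_thr, p_thr, tol)
            rows.append({
                "fiber": fiber, "effect": effect,
                "fiber_onset_mA": n_thr.onset_current,
                "effect_onset_mA": p_thr.onset_current,
                "onset_diff_mA": rep.onset_difference,
                "saturation_diff_mA": rep.saturation_difference,
                "tolerance_mA": tol,
                "aligned": rep.aligned,
                "reason": rep.reason,
            })
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# run_all
# ---------------------------------------------------------------------------

def run_all(config: PipelineConfig | None = None) -> ReportBundle:
    """Run the full pipeline; deterministic given ``config.seed``."""
    config = config or PipelineConfig()
    config.validate()
    notes = [f"config digest {config.digest()}", f"seed {config.seed}"]

    log.info("stage simulate (preset=%s seed=%d)", config.preset, config.seed)
    if config.session_path is not None:
        session = read_session(config.session_path)
        notes.append(f"session loaded from {config.session_path}")
    else:
        session, _ = synth.generate_session(preset_config(config.preset),
                                            seed=config.seed)
        notes.append(f"session simulated: preset {config.preset}, "
                     f"{len(session.events)} events")

    log.info("stage extract-ecaps")
    table, _ = ecaps.compute_activations(session)

    log.info("stage physio")
    physio_df = physio.compute_physio_responses(session)

    log.info("stage drc")
    thresholds = fiber_thresholds_table(table, config.fibers,
                                        config.channel_id)
    alignment = alignment_table(table, physio_df, config.fibers,
                                config.channel_id)

    log.info("stage dosing-map")
    dose_map = None
    optimum = None
    axis_cols = [c for c in ("current_mA", "frequency_hz", "duration_s",
                             "pulse_width_us")
                 if physio_df[c].nunique() > 1][:2]
    if len(axis_cols) == 2:
        dose_map = dosing.build_dose_map(physio_df,
                                         (axis_cols[0], axis_cols[1]),
                                         grid_n=config.grid_n)
        dosing.feasibility_mask(dose_map, config.constraints)
        if dose_map.mask.any():
            optimum = dosing.constrained_optimum(dose_map, config.objective)
        else:
            notes.append("no feasible dose under the configured constraints")
    else:
        notes.append("dose map skipped: fewer than two varying parameters")

    log.info("stage latent")
    latent = None
    vectors = dosing.build_activation_vectors(table,
                                              channel_id=config.channel_id)
    if len(vectors) >= 3:
        latent = dosing.fit_latent_space(vectors)
    else:
        notes.append(f"latent space skipped: {len(vectors)} location(s), "
                     "need >= 3")

    return ReportBundle(config=config, session=session, activations=table,
                        physio=physio_df, thresholds=thresholds,
                        alignment=alignment, dose_map=dose_map,
                        optimum=optimum, latent=latent, notes=notes)


# ---------------------------------------------------------------------------
# Report rendering and bundle output
# ---------------------------------------------------------------------------

def _format_threshold(row: pd.Series) -> str:
    if row["nominal"]:
        return (f"> {row['max_tested_mA']:.2f} mA "
                f"(nominal {drcmodels.NOMINAL_THRESHOLD_MA:.0f} mA)")
    return f"{row['onset_mA']:.3f} mA"


def render_report(bundle: ReportBundle) -> str:
    """Byte-stable human-readable summary of a report bundle."""
    lines = [
        f"ecapkit report — subject {bundle.session.subject_id}",
        f"events: {len(bundle.session.events)}",
        "",
        "Neural thresholds (onset current, 15% of max activation):",
    ]
    if bundle.thresholds.empty:
        lines.append("  (none computed)")
    for _, row in bundle.thresholds.iterrows():
        lines.append(
            f"  {row['fiber']:<8s} {row['contact_pair']}/{row['polarity']}"
            f" pw {row['pulse_width_us']:.0f} us: {_format_threshold(row)}")
    lines += ["", "Aligned biomarker pairs (DRC alignment criterion):"]
    aligned = bundle.alignment[bundle.alignment["aligned"]] \
        if not bundle.alignment.empty else bundle.alignment
    if aligned is None or len(aligned) == 0:
        lines.append("  (none)")
    else:
        for _, row in aligned.iterrows():
            lines.append(
                f"  {row['fiber']} <-> {row['effect']}: onset diff "
                f"{row['onset_diff_mA']:.3f} mA (tol "
                f"{row['tolerance_mA']:.3f} mA)")
    lines.append("")
    if bundle.optimum is not None:
        (i, j), (v1, v2), val = bundle.optimum
        n1, n2 = bundle.dose_map.axis_names
        cons = ", ".join(f"{c.metric} {c.comparator} {c.bound}"
                         for c in bundle.dose_map.constraints) or "none"
        lines.append(
            f"Constrained dose recommendation: {n1} = {v1:.3g}, "
            f"{n2} = {v2:.3g} (on-target {val:.2f}) under constraints: "
            f"{cons}")
    elif bundle.dose_map is not None:
        binding = ", ".join(f"{c.metric} {c.comparator} {c.bound}"
                            for c in bundle.dose_map.constraints)
        lines.append(f"No feasible dose; binding constraints: {binding}")
    else:
        lines.append("Dose map not computed.")
    lines.append("")
    for note in bundle.notes:
        lines.append(f"note: {note}")
    return "\n".join(lines) + "\n"


def write_bundle(bundle: ReportBundle, out_dir: str | Path) -> Path:
    """Write every stage output of a bundle under ``out_dir``."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    write_session(bundle.session, out / "session")
    bundle.activations.to_csv(out / "activations.csv", index=False)
    bundle.physio.to_csv(out / "physio.csv", index=False)
    bundle.thresholds.to_csv(out / "thresholds.csv", index=False)
    bundle.alignment.to_csv(out / "alignment.csv", index=False)
    if bundle.dose_map is not None:
        dm = bundle.dose_map
        pd.DataFrame(dm.on_target, index=dm.axes[0],
                     columns=dm.axes[1]).to_csv(out / "dose_map.csv")
        pd.DataFrame(dm.mask, index=dm.axes[0],
                     columns=dm.axes[1]).to_csv(out / "dose_mask.csv")
    if bundle.optimum is not None:
        cell, values, val = bundle.optimum
        (out / "optimum.json").write_text(json.dumps({
            "cell": list(cell),
            "axes": list(bundle.dose_map.axis_names),
            "values": list(values),
            "on_target": val,
        }, indent=1) + "\n")
    if bundle.latent is not None:
        bundle.latent.projections.to_csv(out / "latent.csv", index=False)
        pd.DataFrame(bundle.latent.loadings).to_csv(out / "loadings.csv",
                                                    index=False)
    report_path = out / "report.txt"
    report_path.write_text(render_report(bundle))
    (out / "bundle.json").write_text(json.dumps({
        "config_digest": bundle.config.digest(),
        "seed": bundle.config.seed,
        "notes": bundle.notes,
        "files": sorted(p.name for p in out.iterdir()),
    }, indent=1, sort_keys=True) + "\n")
    return report_path


__all__ = [
    "PipelineConfig", "PRESETS", "ReportBundle", "alignment_table",
    "fiber_thresholds_table", "physio_drc_values", "preset_config",
    "render_report", "run_all", "write_bundle",
]
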