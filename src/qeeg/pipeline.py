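"""End-to-end study orchestration: recordings -> metrics -> group tables.

For each participant the eyes-open recording of every exposure is cleaned,
and three headline metrics are computed: per-band electrode power, alpha
envelope MI global efficiency (binarized against that participant's air
baseline), and DMN recurrence complexity (masked by that participant's air
baseline).  Group statistics pair every oxygen exposure against the air
baseline (Bonferroni family per metric) and run spatiospectral
cluster-permutation tests on the band-power and MI nodal-strength maps.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from qeeg.complexity import channel_complexity, dmn_complexity
from qeeg.connectivity import binarize, connectivity_matrix, global_efficiency
from qeeg.io import (
    EXPOSURES,
    O2_EXPOSURES,
    Recording,
    StudyConfig,
    logger,
    read_recording,
)
from qeeg.layout import ChannelLayout, default_layout
from qeeg.preprocess import preprocess_recording
from qeeg.spectral import DEFAULT_BANDS, BandDefinition, band_power_map
from qeeg.stats import (
    PairedComparison,
    PsychometricRecord,
    cluster_permutation,
    paired_compare,
    psychometric_impairment,
)
from qeeg.synth import SyntheticStudy

METRICS = ("global_efficiency", "dmn_complexity", "psychometric_impairment")


@dataclass
class StudyResult:
    """Per-participant metric table plus all group-level statistics."""

    metrics: pd.DataFrame
    comparisons: list[PairedComparison] = field(default_factory=list)
    clusters: dict[str, dict] = field(default_factory=dict)
    band_power: dict[tuple[str, str], pd.DataFrame] = field(default_factory=dict)
    excluded: dict[str, str] = field(default_factory=dict)

    def to_dict(self) -> dict:
        comp = [
            {k: (list(v) if isinstance(v, tuple) else v)
             for k, v in dataclasses.asdict(c).items()}
            for c in self.comparisons
        ]
        return {
            "metrics": self.metrics.round(10).to_dict(orient="list"),
            "comparisons": comp,
            "clusters": self.clusters,
            "excluded": dict(sorted(self.excluded.items())),
        }

    def to_json(self, path: str | Path | None = None) -> str:
        text = json.dumps(self.to_dict(), sort_keys=True, indent=1)
        if path is not None:
            Path(path).write_text(text)
        return text


def _bands_from_config(cfg: StudyConfig) -> tuple[BandDefinition, ...]:
    return tuple(BandDefinition(name, lo, hi) for name, (lo, hi) in cfg.bands.items())


def _cluster_summary(result) -> dict:
    return {
        "n_clusters": len(result.clusters),
        "significant": [
            {
                "mass": c.mass,
                "p": c.p,
                "cohens_d": c.cohens_d,
                "n_nodes": len(c.nodes),
                "nodes": [list(nd) for nd in c.nodes],
            }
            for c in result.significant
        ],
        "min_p": min((c.p for c in result.clusters), default=1.0),
    }


def analyze_participant(
    recordings: dict[str, Recording],
    cfg: StudyConfig,
    layout: ChannelLayout,
) -> dict:
    """All per-exposure metrics for one participant.

    ``recordings`` maps exposure -> eyes-open Recording and must include
    the air baseline (the binarization threshold and DMN mask come from
    it).
    """
    if "air_baseline" not in recordings:
        raise KeyError("air baseline recording missing")
    bands = _bands_from_config(cfg)
    epochs = {}
    for exposure, rec in recordings.items():
        ep, _ = preprocess_recording(rec, cfg)
        epochs[exposure] = ep

    conn = {e: connectivity_matrix(ep, layout, cfg) for e, ep in epochs.items()}
    baseline_conn = conn["air_baseline"]
    efficiency = {
        e: global_efficiency(binarize(m, baseline_conn, cfg.binarize_fraction))
        for e, m in conn.items()
    }
    maps = {e: channel_complexity(ep, cfg) for e, ep in epochs.items()}
    masked = dmn_complexity(maps, "air_baseline", cfg.dmn_entropy_threshold)
    power = {e: band_power_map(ep, bands) for e, ep in epochs.items()}
    return {
        "efficiency": efficiency,
        "dmn": {e: m.dmn_complexity for e, m in masked.items()},
        "band_power": power,
        "mi_strength": {e: m.nodal_strength() for e, m in conn.items()},
    }


def _group_statistics(
    metrics: pd.DataFrame,
    band_power: dict[tuple[str, str], pd.DataFrame],
    mi_strength: dict[tuple[str, str], np.ndarray],
    layout: ChannelLayout,
    cfg: StudyConfig,
) -> tuple[list[PairedComparison], dict[str, dict]]:
    comparisons: list[PairedComparison] = []
    pids = sorted(metrics["participant_id"].unique())
    wide = metrics.set_index(["participant_id", "exposure"])
    # contrast only the oxygen exposures recorded for every participant
    contrasts = [
        e for e in O2_EXPOSURES
        if all((p, e) in wide.index for p in pids)
    ]
    for metric in METRICS:
        if metric not in metrics.columns or metrics[metric].isna().all():
            continue
        base = wide.loc[[(p, "air_baseline") for p in pids], metric].to_numpy()
        for exposure in contrasts:
            vals = wide.loc[[(p, exposure) for p in pids], metric].to_numpy()
            comparisons.append(
                paired_compare(
                    vals,
                    base,
                    metric=metric,
                    pair=(exposure, "air_baseline"),
                    family_size=cfg.family_size,
                    alpha=cfg.alpha,
                )
            )

    clusters: dict[str, dict] = {}
    rng = np.random.default_rng(cfg.seed)
    for exposure in contrasts:
        bp_a = np.stack([band_power[(p, exposure)].to_numpy() for p in pids])
        bp_b = np.stack([band_power[(p, "air_baseline")].to_numpy() for p in pids])
        res = cluster_permutation(
            bp_a, bp_b, layout.adjacency,
            n_permutations=cfg.n_permutations,
            cluster_alpha=cfg.cluster_alpha, alpha=cfg.alpha, seed=rng,
        )
        clusters[f"band_power:{exposure}"] = _cluster_summary(res)
        mi_a = np.stack([mi_strength[(p, exposure)] for p in pids])[:, :, None]
        mi_b = np.stack([mi_strength[(p, "air_baseline")] for p in pids])[:, :, None]
        res = cluster_permutation(
            mi_a, mi_b, layout.adjacency,
            n_permutations=cfg.n_permutations,
            cluster_alpha=cfg.cluster_alpha, alpha=cfg.alpha, seed=rng,
        )
        clusters[f"mi_strength:{exposure}"] = _cluster_summary(res)
    return comparisons, clusters


def run_study_dataset(
    study: SyntheticStudy | dict,
    cfg: StudyConfig | None = None,
    layout: ChannelLayout | None = None,
    condition: str = "eyes_open",
) -> StudyResult:
    """Run the full analysis on an in-memory dataset.

    Accepts a ``SyntheticStudy`` or a dict with the same ``recordings`` /
    ``psychometrics`` fields.  Only the eyes-open recordings enter the
    headline metrics; participants without an air baseline are excluded
    with a logged reason.
    """
    cfg = cfg or StudyConfig()
    layout = layout or default_layout()
    recordings = study.recordings if not isinstance(study, dict) else study["recordings"]
    psychos = study.psychometrics if not isinstance(study, dict) else study.get("psychometrics", [])
    psycho_map: dict[tuple[str, str], PsychometricRecord] = {
        (p.participant_id, p.exposure): p for p in psychos
    }

    pids = sorted({k[0] for k in recordings})
    rows = []
    band_power: dict[tuple[str, str], pd.DataFrame] = {}
    mi_strength: dict[tuple[str, str], np.ndarray] = {}
    excluded: dict[str, str] = {}
    for pid in pids:
        per_exposure = {
            e: recordings[(pid, e, condition)]
            for e in EXPOSURES
            if (pid, e, condition) in recordings
        }
        if "air_baseline" not in per_exposure:
            excluded[pid] = "missing air baseline"
            logger.warning("excluding %s: missing air baseline", pid)
            continue
        try:
            res = analyze_participant(per_exposure, cfg, layout)
        except Exception as exc:
            excluded[pid] = f"analysis failure: {exc}"
            logger.warning("excluding %s: %s", pid, exc)
            continue
        for exposure in per_exposure:
            psy = psycho_map.get((pid, exposure))
            rows.append(
                {
                    "participant_id": pid,
                    "exposure": exposure,
                    "global_efficiency": res["efficiency"][exposure],
                    "dmn_complexity": res["dmn"][exposure],
                    "psychometric_impairment": (
                        psychometric_impairment(psy, cfg.rt_normalizer)
                        if psy is not None
                        else np.nan
                    ),
                }
            )
            band_power[(pid, exposure)] = res["band_power"][exposure]
            mi_strength[(pid, exposure)] = res["mi_strength"][exposure]

    metrics = pd.DataFrame(rows).sort_values(
        ["participant_id", "exposure"], ignore_index=True
    )
    analyzed = sorted(metrics["participant_id"].unique()) if len(metrics) else []
    complete = [
        p for p in analyzed
        if {"air_baseline"} < set(metrics.loc[metrics.participant_id == p, "exposure"])
    ]
    comparisons: list[PairedComparison] = []
    clusters: dict[str, dict] = {}
    if len(complete) >= 5:
        sub = metrics[metrics.participant_id.isin(complete)]
        comparisons, clusters = _group_statistics(
            sub, band_power, mi_strength, layout, cfg
        )
    else:
        logger.warning("only %d complete participants: group statistics skipped",
                       len(complete))
    return StudyResult(
        metrics=metrics,
        comparisons=comparisons,
        clusters=clusters,
        band_power=band_power,
        excluded=excluded,
    )


def load_study_directory(
    root: str | Path,
    layout: ChannelLayout | None = None,
) -> dict:
    """Load a study from the documented directory convention.

    ``root/<participant>/<exposure>/<condition>.bdf`` (or ``.edf``) plus an
    optional ``root/<participant>/psychometrics.csv`` with columns
    ``exposure, item, reaction_time, correct`` (reaction_time empty where
    the item timed out).
    """
    root = Path(root)
    layout = layout or default_layout()
    recordings: dict[tuple[str, str, str], Recording] = {}
    psychometrics: list[PsychometricRecord] = []
    for pdir in sorted(p for p in root.iterdir() if p.is_dir()):
        pid = pdir.name
        for edir in sorted(e for e in pdir.iterdir() if e.is_dir()):
            if edir.name not in EXPOSURES:
                logger.warning("skipping unknown exposure directory %s", edir)
                continue
            for f in sorted(edir.glob("*.[be]df")):
                condition = f.stem
                recordings[(pid, edir.name, condition)] = read_recording(
                    f, layout,
                    participant_id=pid, exposure=edir.name, condition=condition,
                )
        csv = pdir / "psychometrics.csv"
        if csv.exists():
            table = pd.read_csv(csv)
            for exposure, grp in table.groupby("exposure"):
                grp = grp.sort_values("item")
                psychometrics.append(
                    PsychometricRecord(
                        participant_id=pid,
                        exposure=str(exposure),
                        reaction_times=grp["reaction_time"].to_numpy(dtype=float),
                        correct=grp["correct"].fillna(False).to_numpy(dtype=bool),
                    )
                )
    return {"recordings": recordings, "psychometrics": psychometrics}


def run_study(
    root: str | Path,
    cfg: StudyConfig | None = None,
    layout: ChannelLayout | None = None,
) -> StudyResult:
    """Load a study directory and run the full analysis."""
    layout = layout or default_layout()
    dataset = load_study_directory(root, layout)
    return run_study_dataset(dataset, cfg, layout)
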