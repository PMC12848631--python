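"""Seeded synthetic cohorts: connectomes with planted brain-behavior edges,
and two-arm headache-diary trials with known ground truth.

The connectome generator works directly in Fisher-z space.  A per-subject
latent trait u ~ N(0, 1) couples a small planted set of edges to the
behavioral change score:

* planted positive edge:  background_mean + gamma * u + N(0, edge_noise_sd)
* planted negative edge:  background_mean - gamma * u + N(0, edge_noise_sd)
* every other edge:       background_mean + N(0, background_sd)
* behavior:               behavior_mean + behavior_slope * u + N(0, behavior_noise_sd)

so the planted edges carry a known, tunable correlation with behavior and
everything else is exchangeable noise.  A secondary helper generates node
time series with a shared latent signal so the correlation/Fisher-z path
can be exercised end to end.

The trial generator emulates a two-arm design with a 28-day baseline and a
28-day treatment period: day-wise headache draws at an arm-specific
treatment rate, attack-level duration/VAS/medication fields, day-level
missingness, and subject-level dropout that truncates the treatment diary.

One global seed expands into independent per-purpose substreams (edge
placement, latent traits, matrices, behavior, diaries) so that, e.g.,
adding subjects does not perturb earlier draws.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .connectome import (
    AtlasLabels,
    ConnectivityMatrix,
    EdgeIndexMap,
    NodeTimeSeries,
    devectorize_edges,
    write_atlas_labels,
    write_matrix,
)

__all__ = [
    "ConnectomeSimConfig",
    "TrialSimConfig",
    "GroundTruth",
    "ConnectomeCohort",
    "TrialCohort",
    "simulate_connectome_cohort",
    "simulate_node_timeseries",
    "simulate_trial",
    "write_fixtures",
    "make_synthetic_atlas",
    "DIARY_COLUMNS",
]

#: canonical networks used for the synthetic atlas (8-network convention)
CANONICAL_NETWORKS = (
    "medial_frontal",
    "frontoparietal",
    "DMN",
    "motor",
    "visual1",
    "visual2",
    "visual_association",
    "SC",
)

DIARY_COLUMNS = [
    "subject_id",
    "arm",
    "period",
    "day_index",
    "recorded",
    "headache",
    "duration_hours",
    "meets_icdh3",
    "vas",
    "med_class",
]


class SimulationConfigError(ValueError):
    """Invalid simulation configuration."""


@dataclass
class ConnectomeSimConfig:
    """Connectome cohort with planted brain-behavior edges.

    Defaults are the documented study conditions used throughout the test
    suite: 60 subjects on a 60-node parcellation with 15 positive and 15
    negative planted edges, background Fisher z of 0.3 +/- 0.15 (typical
    resting-state magnitudes), coupling 0.1 z-units per latent SD against
    0.05 edge noise, and a behavior slope of 3 score units per latent SD
    against unit score noise.
    """

    n_subjects: int = 60
    n_nodes: int = 60
    n_pos_edges: int = 15
    n_neg_edges: int = 15
    coupling: float = 0.1            # gamma, Fisher-z units per latent SD
    edge_noise_sd: float = 0.05      # Fisher-z units
    background_mean: float = 0.3     # Fisher-z units
    background_sd: float = 0.15      # Fisher-z units
    behavior_mean: float = 0.0       # score units
    behavior_slope: float = 3.0      # beta, score units per latent SD
    behavior_noise_sd: float = 1.0   # score units
    behavior_name: str = "vas_change"
    seed: int = 0

    def validate(self) -> None:
        emap = EdgeIndexMap(self.n_nodes)
        if self.n_subjects < 2:
            raise SimulationConfigError("need at least 2 subjects")
        if self.n_pos_edges < 0 or self.n_neg_edges < 0:
            raise SimulationConfigError("planted edge counts must be non-negative")
        if self.n_pos_edges + self.n_neg_edges > emap.n_edges:
            raise SimulationConfigError(
                f"{self.n_pos_edges}+{self.n_neg_edges} planted edges exceed "
                f"{emap.n_edges} available edges on {self.n_nodes} nodes"
            )
        for name in ("edge_noise_sd", "background_sd", "behavior_noise_sd"):
            if getattr(self, name) < 0:
                raise SimulationConfigError(f"{name} must be >= 0")


@dataclass
class GroundTruth:
    """What the generator planted: edge sets, latent traits, behavior."""

    planted_pos_edges: np.ndarray
    planted_neg_edges: np.ndarray
    latent_traits: np.ndarray
    behavior: np.ndarray


@dataclass
class ConnectomeCohort:
    subject_ids: list[str]
    matrices: list[ConnectivityMatrix]
    behavior: np.ndarray
    ground_truth: GroundTruth
    config: ConnectomeSimConfig

    def edge_matrix(self) -> np.ndarray:
        """Subjects x edges matrix of upper-triangle Fisher-z values."""
        from .connectome import vectorize_edges

        emap = EdgeIndexMap(self.config.n_nodes)
        return np.stack([vectorize_edges(m, emap) for m in self.matrices])


def simulate_connectome_cohort(config: ConnectomeSimConfig) -> ConnectomeCohort:
    """Generate a seeded cohort of symmetric Fisher-z matrices plus behavior.

    Identical seeds give bit-identical output.  The planted positive and
    negative edge sets are disjoint by construction.
    """
    config.validate()
    emap = EdgeIndexMap(config.n_nodes)
    ss = np.random.SeedSequence(config.seed)
    edges_ss, latent_ss, matrices_ss, behavior_ss = ss.spawn(4)

    rng_edges = np.random.default_rng(edges_ss)
    n_planted = config.n_pos_edges + config.n_neg_edges
    chosen = rng_edges.choice(emap.n_edges, size=n_planted, replace=False)
    pos = np.sort(chosen[: config.n_pos_edges])
    neg = np.sort(chosen[config.n_pos_edges:])

    u = np.random.default_rng(latent_ss).standard_normal(config.n_subjects)
    eps = np.random.default_rng(behavior_ss).standard_normal(config.n_subjects)
    behavior = config.behavior_mean + config.behavior_slope * u + config.behavior_noise_sd * eps

    matrices = []
    subject_streams = matrices_ss.spawn(config.n_subjects)
    for i, sub_ss in enumerate(subject_streams):
        rng = np.random.default_rng(sub_ss)
        v = config.background_mean + config.background_sd * rng.standard_normal(emap.n_edges)
        planted_noise = config.edge_noise_sd * rng.standard_normal(n_planted)
        v[pos] = config.background_mean + config.coupling * u[i] + planted_noise[: config.n_pos_edges]
        v[neg] = config.background_mean - config.coupling * u[i] + planted_noise[config.n_pos_edges:]
        matrices.append(devectorize_edges(v, emap))

    truth = GroundTruth(
        planted_pos_edges=pos,
        planted_neg_edges=neg,
        latent_traits=u,
        behavior=behavior.copy(),
    )
    subject_ids = [f"sub-{i:03d}" for i in range(config.n_subjects)]
    return ConnectomeCohort(subject_ids, matrices, behavior, truth, config)


def simulate_node_timeseries(
    n_timepoints: int = 200,
    n_nodes: int = 10,
    shared_strength: float = 0.5,
    seed: int | np.random.SeedSequence = 0,
) -> NodeTimeSeries:
    """Node time series sharing a common latent signal.

    Each node is ``shared_strength * c + sqrt(1 - shared_strength^2) * noise``
    with a common standard-normal course c, so every node pair has expected
    Pearson correlation ``shared_strength ** 2``.  Used to exercise the
    correlation -> Fisher-z pipeline end to end.
    """
    if not (0 <= shared_strength < 1):
        raise SimulationConfigError("shared_strength must be in [0, 1)")
    rng = np.random.default_rng(seed)
    common = rng.standard_normal((n_timepoints, 1))
    noise = rng.standard_normal((n_timepoints, n_nodes))
    values = shared_strength * common + np.sqrt(1 - shared_strength**2) * noise
    return NodeTimeSeries(values)


# ---------------------------------------------------------------------------
# trial generator


def _default_score_effects() -> dict[str, dict[str, tuple[float, float]]]:
    # (mean change, SD) per arm; means follow the scale of the trial's
    # reported change scores, SDs chosen as plausible subject-level spreads.
    return {
        "vas_change": {"real": (-2.0, 1.5), "sham": (-1.2, 1.5)},
        "hit6_change": {"real": (-8.3, 6.5), "sham": (-5.4, 6.5)},
        "msq_rr_change": {"real": (20.0, 12.0), "sham": (8.6, 12.0)},
        "msq_rp_change": {"real": (15.0, 12.0), "sham": (10.0, 12.0)},
        "msq_ef_change": {"real": (13.3, 10.0), "sham": (7.0, 10.0)},
    }


@dataclass
class TrialSimConfig:
    """Two-arm 28-day-baseline / 28-day-treatment diary trial.

    ``baseline_migraine_rate`` is the expected number of headache days per
    28-day baseline; ``real_effect`` / ``sham_effect`` multiply that rate
    during treatment (0.55 means the real arm keeps 55% of its baseline
    attack rate, i.e. a 45% reduction).  Eligibility mirrors the trial
    population: a subject's baseline must contain at least
    ``min_baseline_migraine_days`` migraine days (resampled until true).
    """

    n_per_arm: int = 60
    baseline_migraine_rate: float = 7.0      # expected headache days per 28
    real_effect: float = 0.55                # multiplicative treatment rate
    sham_effect: float = 0.80
    long_duration_prob: float = 0.85         # P(headache lasts >= 4 h)
    duration_scale_hours: float = 4.0        # mean excess over 4 h (exponential)
    icdh3_prob: float = 0.95                 # P(headache meets ICHD-3 criteria)
    med_use_prob: float = 0.5                # P(migraine-specific medication | headache day)
    nonspecific_med_prob: float = 0.3        # P(nonspecific medication | headache day, no specific)
    missing_day_prob: float = 0.02
    dropout_prob: float = 0.05
    min_baseline_migraine_days: int = 2
    score_effects: dict = field(default_factory=_default_score_effects)
    seed: int = 0

    def validate(self) -> None:
        if self.n_per_arm < 2:
            raise SimulationConfigError("need at least 2 subjects per arm")
        if self.baseline_migraine_rate <= 0:
            raise SimulationConfigError("baseline rate must be positive")
        for name in ("real_effect", "sham_effect"):
            v = getattr(self, name)
            if not (0 < v <= 1):
                raise SimulationConfigError(f"{name} must be in (0, 1]")
        for name in (
            "long_duration_prob",
            "icdh3_prob",
            "med_use_prob",
            "nonspecific_med_prob",
            "missing_day_prob",
            "dropout_prob",
        ):
            v = getattr(self, name)
            if not (0 <= v <= 1):
                raise SimulationConfigError(f"{name} must be in [0, 1]")
        if self.baseline_migraine_rate / 28.0 > 1:
            raise SimulationConfigError("baseline rate exceeds 28 days per period")


@dataclass
class TrialCohort:
    diary: pd.DataFrame
    subjects: pd.DataFrame
    config: TrialSimConfig


def _qualifies(headache, duration, icdh3, med):
    return (headache & (duration >= 4) & icdh3) | (med == "migraine_specific")


def _simulate_period(rng: np.random.Generator, cfg: TrialSimConfig, rate: float):
    """28 days of diary fields (before missingness).  Returns a dict of arrays."""
    p_day = rate / 28.0
    headache = rng.random(28) < p_day
    n_h = int(headache.sum())
    long = rng.random(28) < cfg.long_duration_prob
    dur_long = 4.0 + rng.exponential(cfg.duration_scale_hours, 28)
    dur_short = rng.uniform(1.0, 4.0, 28)
    duration = np.where(headache, np.where(long, dur_long, dur_short), 0.0)
    duration = np.round(duration, 1)
    icdh3 = headache & (rng.random(28) < cfg.icdh3_prob)
    vas = np.where(headache, np.clip(np.round(rng.normal(6.0, 1.5, 28)), 1, 10), 0.0)
    med = np.full(28, "none", dtype=object)
    spec = headache & (rng.random(28) < cfg.med_use_prob)
    nonspec = headache & ~spec & (rng.random(28) < cfg.nonspecific_med_prob)
    med[spec] = "migraine_specific"
    med[nonspec] = "nonspecific"
    return {
        "headache": headache,
        "duration": duration,
        "icdh3": icdh3,
        "vas": vas,
        "med": med,
        "n_headache": n_h,
    }


def simulate_trial(config: TrialSimConfig) -> TrialCohort:
    """Generate a seeded two-arm diary trial.

    With ``missing_day_prob = dropout_prob = 0`` every diary has exactly 56
    rows (28 baseline + 28 treatment).  Missing days are kept as rows with
    ``recorded = 0`` and blank clinical fields; dropout removes treatment
    rows after the (random) dropout day.
    """
    config.validate()
    ss = np.random.SeedSequence(config.seed)
    diary_ss, score_ss = ss.spawn(2)
    n_total = 2 * config.n_per_arm
    subject_streams = diary_ss.spawn(n_total)
    rng_scores = np.random.default_rng(score_ss)

    diary_rows: list[dict] = []
    subject_rows: list[dict] = []
    for i in range(n_total):
        arm = "real" if i < config.n_per_arm else "sham"
        sid = f"sub-{i:03d}"
        rng = np.random.default_rng(subject_streams[i])
        effect = config.real_effect if arm == "real" else config.sham_effect

        # eligibility: >= min_baseline_migraine_days migraine days at baseline
        for _ in range(1000):
            base = _simulate_period(rng, config, config.baseline_migraine_rate)
            n_mig = int(
                _qualifies(base["headache"], base["duration"], base["icdh3"], base["med"]).sum()
            )
            if n_mig >= config.min_baseline_migraine_days:
                break
        else:  # pragma: no cover - astronomically unlikely at sane configs
            raise SimulationConfigError("could not satisfy baseline eligibility")
        treat = _simulate_period(rng, config, config.baseline_migraine_rate * effect)

        dropout = bool(rng.random() < config.dropout_prob)
        dropout_day = int(rng.integers(1, 28)) if dropout else 0
        missing_base = rng.random(28) < config.missing_day_prob
        missing_treat = rng.random(28) < config.missing_day_prob

        for period, data, missing in (
            ("baseline", base, missing_base),
            ("treatment", treat, missing_treat),
        ):
            for d in range(28):
                day = d + 1
                if period == "treatment" and dropout and day > dropout_day:
                    continue  # dropout truncates the treatment diary
                if missing[d]:
                    diary_rows.append(
                        {
                            "subject_id": sid,
                            "arm": arm,
                            "period": period,
                            "day_index": day,
                            "recorded": 0,
                            "headache": np.nan,
                            "duration_hours": np.nan,
                            "meets_icdh3": np.nan,
                            "vas": np.nan,
                            "med_class": "",
                        }
                    )
                else:
                    diary_rows.append(
                        {
                            "subject_id": sid,
                            "arm": arm,
                            "period": period,
                            "day_index": day,
                            "recorded": 1,
                            "headache": int(data["headache"][d]),
                            "duration_hours": float(data["duration"][d]),
                            "meets_icdh3": int(data["icdh3"][d]),
                            "vas": float(data["vas"][d]),
                            "med_class": str(data["med"][d]),
                        }
                    )

        row = {"subject_id": sid, "arm": arm, "dropout": int(dropout), "dropout_day": dropout_day}
        for score, arms in config.score_effects.items():
            mean, sd = arms[arm]
            row[score] = np.nan if dropout else float(rng_scores.normal(mean, sd))
        subject_rows.append(row)

    diary = pd.DataFrame(diary_rows, columns=DIARY_COLUMNS)
    subjects = pd.DataFrame(subject_rows)
    return TrialCohort(diary=diary, subjects=subjects, config=config)


# ---------------------------------------------------------------------------
# fixtures on disk


def make_synthetic_atlas(n_nodes: int) -> AtlasLabels:
    """Assign nodes to the canonical networks in contiguous blocks."""
    labels = [CANONICAL_NETWORKS[(k * len(CANONICAL_NETWORKS)) // n_nodes] for k in range(n_nodes)]
    table = pd.DataFrame(
        {"node_id": np.arange(1, n_nodes + 1), "network_label": labels}
    ).set_index("node_id")
    return AtlasLabels(table)


def write_fixtures(
    directory: str | Path,
    connectome: ConnectomeCohort | None = None,
    trial: TrialCohort | None = None,
    atlas: AtlasLabels | None = None,
) -> Path:
    """Write a cohort to disk in the package's plain-text formats.

    Emits per-subject matrix TSVs, a cohort manifest CSV, an atlas-label
    CSV, a ground-truth JSON sidecar, and (when a trial cohort is given)
    diary and subject CSVs.  Returns the manifest path (or the directory
    when only a trial is written).  Output is byte-identical for identical
    cohorts.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    manifest_path = directory / "manifest.csv"

    if connectome is not None:
        cfg = connectome.config
        mat_dir = directory / "matrices"
        mat_dir.mkdir(exist_ok=True)
        rel_paths = []
        for sid, mat in zip(connectome.subject_ids, connectome.matrices):
            rel = f"matrices/{sid}.tsv"
            write_matrix(mat, directory / rel)
            rel_paths.append(rel)
        manifest = pd.DataFrame(
            {
                "subject_id": connectome.subject_ids,
                "arm": "real",
                "matrix_path": rel_paths,
                cfg.behavior_name: connectome.behavior,
            }
        )
        manifest.to_csv(manifest_path, index=False)

        if atlas is None:
            atlas = make_synthetic_atlas(cfg.n_nodes)
        write_atlas_labels(atlas, directory / "atlas_labels.csv")

        truth = connectome.ground_truth
        sidecar = {
            "planted_pos_edges": truth.planted_pos_edges.tolist(),
            "planted_neg_edges": truth.planted_neg_edges.tolist(),
            "latent_traits": truth.latent_traits.tolist(),
            "behavior": truth.behavior.tolist(),
            "config": asdict(cfg),
        }
        (directory / "ground_truth.json").write_text(json.dumps(sidecar, indent=2, sort_keys=True))

    if trial is not None:
        trial.diary.to_csv(directory / "diary.csv", index=False)
        trial.subjects.to_csv(directory / "subjects.csv", index=False)
        (directory / "trial_config.json").write_text(
            json.dumps(asdict(trial.config), indent=2, sort_keys=True, default=list)
        )

    return manifest_path if connectome is not None else directory


def load_manifest(path: str | Path) -> pd.DataFrame:
    """Read a cohort manifest CSV and validate its required columns."""
    df = pd.read_csv(path)
    for col in ("subject_id", "arm", "matrix_path"):
        if col not in df.columns:
            raise SimulationConfigError(f"{path}: manifest missing column {col!r}")
    return df


def directory_checksum(directory: str | Path) -> str:
    """SHA-256 over all files (path + content) under a directory; for
    re-runnability checks."""
    directory = Path(directory)
    h = hashlib.sha256()
    for p in sorted(directory.rglob("*")):
        if p.is_file():
            h.update(str(p.relative_to(directory)).encode())
            h.update(p.read_bytes())
    return h.hexdigest()
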