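"""Synthetic desk-scale cohorts with known planted structure.

A linear-Gaussian generator: cue-band powers fluctuate independently around
per-subject baselines; for each planted (cue ROI, item ROI) pair the item
column shares a standardized latent with the cue column at a configured
negative population correlation, drawn per subject and condition.
Behavioral counts are binomial with rates tied to the subject's coupling
contrast, so the sign of the coupling-behavior association is known.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, replace
from typing import Sequence

import numpy as np
from scipy.stats import norm

from .core_network import RoiNodeSet, SubjectData, TrialPowerTable
from .stats import BehavioralRecord

__all__ = ["PlantedPair", "SimulationConfig", "SyntheticCohort",
           "generate_cohort", "null_cohort"]

_RECOG_TRIALS = 200  # recognition-session items per response category


@dataclass(frozen=True)
class PlantedPair:
    cue_roi: str
    item_roi: str
    coupling_R: float
    coupling_NR: float


@dataclass(frozen=True)
class SimulationConfig:
    n_subjects: int = 12
    n_rois: int = 8
    trials_per_condition: tuple[int, int] = (40, 38)  # (R, NR); unequal by default
    planted_pairs: tuple[PlantedPair, ...] = ()
    subject_coupling_sd: float = 0.05
    behavior_link_slope: float = -2.0
    group_effect: float = 0.0
    group_pairs: tuple[tuple[str, str], ...] | None = None  # default: planted pairs
    noise_sd: float = 0.1
    baseline_mean: float = 1.0
    baseline_sd: float = 0.1
    seed: int = 0
    roi_labels: tuple[str, ...] | None = None  # default: head of packaged node list

    def resolved_labels(self) -> tuple[str, ...]:
        if self.roi_labels is not None:
            return tuple(self.roi_labels)
        return RoiNodeSet.cortical_default().labels[: self.n_rois]

    def validate(self) -> None:
        if self.n_subjects < 1:
            raise ValueError("n_subjects must be >= 1")
        if min(self.trials_per_condition) < 10:
            raise ValueError("trials_per_condition entries must be >= 10")
        labels = self.resolved_labels()
        if len(labels) != self.n_rois:
            raise ValueError("roi_labels length must equal n_rois")
        item_rois = [p.item_roi for p in self.planted_pairs]
        if len(set(item_rois)) != len(item_rois):
            raise ValueError("planted item ROIs must be distinct")
        for p in self.planted_pairs:
            for g in (p.coupling_R, p.coupling_NR):
                if not -1.0 <= g <= 0.0:
                    raise ValueError(f"couplings must lie in [-1, 0], got {g}")
            if p.cue_roi not in labels or p.item_roi not in labels:
                raise ValueError(f"planted pair {p} references an unknown ROI")
        if self.group_effect < 0:
            raise ValueError("group_effect must be >= 0")


@dataclass
class SyntheticCohort:
    subjects: list
    behavior: list
    manifest: dict


def _coupled_columns(rng, n_trials, mu, nu, noise_sd, pair_idx, gammas):
    """Cue/item trial tables with exact population correlations at the
    planted pairs."""
    p = len(mu)
    z = rng.standard_normal((n_trials, p))  # standardized cue latents
    w = rng.standard_normal((n_trials, p))  # independent item innovations
    cue = mu + noise_sd * z
    item = nu + noise_sd * w
    for (i, j), g in zip(pair_idx, gammas):
        item[:, j] = nu[j] + noise_sd * (g * z[:, i] + np.sqrt(1.0 - g * g) * w[:, j])
    return cue, item


def generate_cohort(config: SimulationConfig) -> SyntheticCohort:
    """Generate trial tables, behavioral counts and a ground-truth manifest.

    Deterministic: the same config (including seed) yields byte-identical
    output.
    """
    config.validate()
    labels = config.resolved_labels()
    label_idx = {lab: k for k, lab in enumerate(labels)}
    pair_idx = [(label_idx[p.cue_roi], label_idx[p.item_roi]) for p in config.planted_pairs]
    group_pairs = (config.group_pairs if config.group_pairs is not None
                   else tuple((p.cue_roi, p.item_roi) for p in config.planted_pairs))

    ss = np.random.SeedSequence(config.seed)
    cohort_rng = np.random.default_rng(ss.spawn(1)[0])
    subject_seeds = ss.spawn(config.n_subjects)

    # half the cohort (rounded down) carries the latent "good" tag
    good_tags = np.zeros(config.n_subjects, dtype=bool)
    good_tags[: config.n_subjects // 2] = True
    cohort_rng.shuffle(good_tags)

    subjects: list[SubjectData] = []
    behavior: list[BehavioralRecord] = []
    manifest_subjects = []
    n_r, n_nr = config.trials_per_condition

    for s, child in enumerate(subject_seeds):
        rng = np.random.default_rng(child)
        sid = f"sub-{s + 1:02d}"
        mu = config.baseline_mean + config.baseline_sd * rng.standard_normal(config.n_rois)
        nu = config.baseline_mean + config.baseline_sd * rng.standard_normal(config.n_rois)

        gammas = {}
        for cond, base in (("R", [p.coupling_R for p in config.planted_pairs]),
                           ("NR", [p.coupling_NR for p in config.planted_pairs])):
            g = np.asarray(base, dtype=float) + config.subject_coupling_sd * rng.standard_normal(
                len(config.planted_pairs))
            if cond == "R" and good_tags[s] and config.group_effect > 0:
                for k, p in enumerate(config.planted_pairs):
                    if (p.cue_roi, p.item_roi) in group_pairs:
                        g[k] -= config.group_effect
            gammas[cond] = np.clip(g, -0.999, 0.0)

        tables = {}
        for cond, n_trials in (("R", n_r), ("NR", n_nr)):
            cue, item = _coupled_columns(rng, n_trials, mu, nu, config.noise_sd,
                                         pair_idx, gammas[cond])
            tables[(cond, "cue_alpha")] = TrialPowerTable(sid, cond, "cue_alpha", labels, cue)
            tables[(cond, "item_gamma")] = TrialPowerTable(sid, cond, "item_gamma", labels, item)
        subjects.append(SubjectData(subject_id=sid, tables=tables))

        # behavioral counts tied to the coupling contrast
        contrast = float(np.mean(gammas["R"] - gammas["NR"])) if pair_idx else 0.0
        memory_latent = ((1.6 if good_tags[s] else 0.4)
                         + 0.2 * rng.standard_normal())
        compliance_latent = (0.6 + config.behavior_link_slope * contrast
                             + 0.15 * rng.standard_normal())
        p_rhit = float(norm.cdf(-0.2 + memory_latent / 2.0))
        p_fa = float(norm.cdf(-0.2 - memory_latent / 2.0))
        p_nrhit = float(norm.cdf(norm.ppf(p_rhit) - compliance_latent))
        rec = BehavioralRecord(
            subject_id=sid,
            r_hits=int(rng.binomial(_RECOG_TRIALS, p_rhit)),
            r_trials=_RECOG_TRIALS,
            nr_hits=int(rng.binomial(_RECOG_TRIALS, p_nrhit)),
            nr_trials=_RECOG_TRIALS,
            false_alarms=int(rng.binomial(_RECOG_TRIALS, p_fa)),
            new_trials=_RECOG_TRIALS,
        )
        behavior.append(rec)
        manifest_subjects.append({
            "subject_id": sid,
            "good_tag": bool(good_tags[s]),
            "gamma_R": [float(x) for x in gammas["R"]],
            "gamma_NR": [float(x) for x in gammas["NR"]],
            "coupling_contrast": contrast,
            "memory_latent": float(memory_latent),
            "compliance_latent": float(compliance_latent),
            "rates": {"r_hit": p_rhit, "nr_hit": p_nrhit, "false_alarm": p_fa},
        })

    manifest = {
        "config": _config_dict(config),
        "roi_labels": list(labels),
        "planted_pairs": [asdict(p) for p in config.planted_pairs],
        "subjects": manifest_subjects,
    }
    return SyntheticCohort(subjects=subjects, behavior=behavior, manifest=manifest)


def _config_dict(config: SimulationConfig) -> dict:
    d = asdict(config)
    d["trials_per_condition"] = list(config.trials_per_condition)
    d["planted_pairs"] = [asdict(p) for p in config.planted_pairs]
    if config.roi_labels is not None:
        d["roi_labels"] = list(config.roi_labels)
    if config.group_pairs is not None:
        d["group_pairs"] = [list(g) for g in config.group_pairs]
    return d


def null_cohort(config: SimulationConfig) -> SyntheticCohort:
    """Cohort with R and NR exchangeable by construction.

    Every planted coupling is set to the mean of its two condition values,
    the group effect is removed, and both conditions get the same trial
    count, so relabeling conditions leaves the distribution unchanged.
    """
    n = min(config.trials_per_condition)
    pairs = tuple(
        replace(p, coupling_R=(p.coupling_R + p.coupling_NR) / 2.0,
                coupling_NR=(p.coupling_R + p.coupling_NR) / 2.0)
        for p in config.planted_pairs
    )
    cfg = replace(config, planted_pairs=pairs, group_effect=0.0,
                  trials_per_condition=(n, n))
    return generate_cohort(cfg)
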