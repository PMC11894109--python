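"""Seeded synthetic microarray cohorts with planted ground truth.

Emulates a prospective ulcerative-colitis biopsy cohort profiled on a
probe-set expression array: ~141 UC/IBDU biopsies plus 17 normal-colon
controls, two labeling-kit batches, an endoscopic Mayo subscore per biopsy,
and clinical covariates (partial/total Mayo, physician's global assessment,
fecal calprotectin) plus a 3-6-month status code.  A latent continuous
disease severity drives a planted subset of probe sets, the calprotectin
transcripts S100A8/S100A9, fecal calprotectin, and the outcome status code,
so every downstream stage can be tested against known truth.

Scale defaults mirror the emulated study (128 UC + 13 IBDU biopsies, 17
controls, Mayo subscore distribution 25/33/49/34); the probe-set count
defaults to 5,000 — a scaled-down array with the same statistical structure.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.special import expit

from .data import CohortBundle

#: Mayo subscore frequencies among the 141 UC+IBDU biopsies (25/33/49/34).
DEFAULT_MAYO_DISTRIBUTION = (25 / 141, 33 / 141, 49 / 141, 34 / 141)

#: Interest-flag groups mirrored on the volcano plot.
INTEREST_FLAGS = ("therapy-target", "inflammasome", "solute-carrier")


@dataclass
class CohortConfig:
    """Generator settings; defaults are the emulated study conditions."""

    n_uc_biopsies: int = 128
    n_ibdu_biopsies: int = 13
    n_controls: int = 17
    n_probesets: int = 5000
    n_signal_probesets: int = 200
    effect_size: float = 1.0  # log2-units per unit latent severity
    mayo_distribution: tuple = DEFAULT_MAYO_DISTRIBUTION
    kit_fraction: float = 0.5  # fraction of samples labeled with kit_B
    kit_offset_sd: float = 0.3  # log2-units, per-probe batch offset
    noise_sd: float = 1.0  # log2-units, scale of per-probe residual SD
    variance_prior_df: float = 4.0  # inverse-chi-square df of per-probe variances
    severity_jitter_sd: float = 0.5  # within-subscore severity spread
    s100_effect_multiplier: float = 2.0  # S100A8/A9 planted effect vs base
    calprotectin_noise_sd: float = 0.6  # log-ug/g lognormal noise
    calprotectin_coupling: float = 0.8  # slope on S100 log2 excess
    calprotectin_fraction: float = 0.5  # biopsies with a stool measurement
    follow_up_fraction: float = 80 / 141  # biopsies with a status code
    status_slope: float = 1.8  # logit slope of Pr(status > 1) on severity
    status_midpoint: float = 1.8  # severity at which Pr(status > 1) = 0.5
    kit_confounded: bool = False  # couple kit assignment to severity
    seed: int = 0

    def validate(self) -> None:
        counts = {
            "n_uc_biopsies": self.n_uc_biopsies,
            "n_ibdu_biopsies": self.n_ibdu_biopsies,
            "n_controls": self.n_controls,
            "n_probesets": self.n_probesets,
            "n_signal_probesets": self.n_signal_probesets,
        }
        for name, value in counts.items():
            if value < 0:
                raise ValueError(f"{name} must be >= 0, got {value}")
        if self.n_signal_probesets > self.n_probesets:
            raise ValueError("n_signal_probesets cannot exceed n_probesets")
        if self.n_signal_probesets < 2:
            raise ValueError(
                "n_signal_probesets must be >= 2: the S100A8/S100A9 "
                "calprotectin pair is always planted"
            )
        weights = np.asarray(self.mayo_distribution, dtype=float)
        if weights.shape != (4,) or abs(weights.sum() - 1.0) > 1e-9:
            raise ValueError("mayo_distribution must be 4 weights summing to 1")


@dataclass
class TruthTable:
    """Planted ground truth for a generated cohort."""

    signal_probesets: list[str]
    effects: dict[str, float]  # probe -> log2-units per unit severity
    severity: dict[str, float]  # sample -> latent severity
    kit_offsets: dict[str, float]  # probe -> kit_B additive offset
    s100a8_probe: str = ""
    s100a9_probe: str = ""

    def to_json(self, path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=1))

    @classmethod
    def from_json(cls, path) -> "TruthTable":
        payload = json.loads(Path(path).read_text())
        return cls(**payload)


def cohort_truth(sidecar_path) -> TruthTable:
    """Load the planted truth for a previously written cohort."""
    path = Path(sidecar_path)
    if not path.exists():
        raise FileNotFoundError(f"no truth available: sidecar {path} does not exist")
    return TruthTable.from_json(path)


def _sample_ids(config: CohortConfig) -> tuple[list[str], list[str], list[str]]:
    uc = [f"UC{i + 1:04d}" for i in range(config.n_uc_biopsies)]
    ibdu = [f"IBDU{i + 1:03d}" for i in range(config.n_ibdu_biopsies)]
    ctrl = [f"CTRL{i + 1:03d}" for i in range(config.n_controls)]
    return uc, ibdu, ctrl


def generate_cohort(config: CohortConfig) -> tuple[CohortBundle, TruthTable]:
    """Generate one seeded cohort plus its ground-truth sidecar.

    The model: per-probe baseline means U(4, 12) log2-units with residual
    variances from a scaled inverse-chi-square law (the standard array
    variance model); latent severity = Mayo subscore + Normal(0, jitter)
    for biopsies and exactly 0 for controls; planted probes shift by
    effect x severity; per-probe kit_B offsets N(0, kit_offset_sd); fecal
    calprotectin lognormal around a curve in the biopsy's own S100A8/A9
    expression; Pr(status code > 1) logistic in severity.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    p = config.n_probesets

    probe_ids = [f"PS{i + 1:06d}" for i in range(p)]
    uc_ids, ibdu_ids, ctrl_ids = _sample_ids(config)
    biopsy_ids = uc_ids + ibdu_ids
    sample_ids = biopsy_ids + ctrl_ids
    n_biopsy, n = len(biopsy_ids), len(sample_ids)

    # --- probe-level parameters ---------------------------------------
    baseline = rng.uniform(4.0, 12.0, size=p)
    d0 = config.variance_prior_df
    probe_sd = config.noise_sd * np.sqrt(d0 / rng.chisquare(d0, size=p))

    signal_idx = rng.choice(p, size=config.n_signal_probesets, replace=False)
    s100a8_probe = probe_ids[signal_idx[0]]
    s100a9_probe = probe_ids[signal_idx[1]]

    effects = np.zeros(p)
    magnitudes = config.effect_size * rng.uniform(0.5, 1.5, size=config.n_signal_probesets)
    signs = rng.choice([-1.0, 1.0], size=config.n_signal_probesets)
    effects[signal_idx] = signs * magnitudes
    # calprotectin subunits: strongly induced, always increased with activity
    effects[signal_idx[0]] = config.s100_effect_multiplier * config.effect_size
    effects[signal_idx[1]] = config.s100_effect_multiplier * config.effect_size

    kit_offsets = rng.normal(0.0, config.kit_offset_sd, size=p)

    # --- sample-level covariates --------------------------------------
    mayo = rng.choice(4, size=n_biopsy, p=np.asarray(config.mayo_distribution))
    severity_biopsy = mayo + rng.normal(0.0, config.severity_jitter_sd, size=n_biopsy)
    severity = np.concatenate([severity_biopsy, np.zeros(config.n_controls)])

    if config.kit_confounded:
        p_kit = expit((severity - 1.5)) * 2 * config.kit_fraction
        p_kit = np.clip(p_kit, 0.0, 1.0)
        in_kit_b = rng.random(n) < p_kit
    else:
        in_kit_b = rng.random(n) < config.kit_fraction

    # --- expression matrix --------------------------------------------
    noise = rng.normal(0.0, 1.0, size=(p, n)) * probe_sd[:, None]
    values = baseline[:, None] + np.outer(effects, severity) + noise
    values = values + np.outer(kit_offsets, in_kit_b.astype(float))

    # --- fecal calprotectin: tracks tissue S100A8/A9 (pre-batch) -------
    s100_rows = [signal_idx[0], signal_idx[1]]
    s100_expr = (
        baseline[s100_rows, None] + np.outer(effects[s100_rows], severity)
        + noise[s100_rows, :]
    ).mean(axis=0)
    s100_excess = s100_expr - baseline[s100_rows].mean()
    log_fc = (
        np.log(120.0)
        + config.calprotectin_coupling * np.log(2.0) * s100_excess
        + rng.normal(0.0, config.calprotectin_noise_sd, size=n)
    )
    fecal_calpro = np.exp(log_fc)

    # --- outcome status code ------------------------------------------
    p_poor = expit(config.status_slope * (severity - config.status_midpoint))
    poor = rng.random(n) < p_poor
    within = rng.integers(0, 2, size=n)
    status = np.where(poor, 2 + within, within)
    has_status = rng.random(n) < config.follow_up_fraction

    # stool calprotectin availability is nested in follow-up: biopsies whose
    # outcome is reassessed also carry the stool measurement, plus a fraction
    # of the rest (mirrors the outcome tables, which report calprotectin
    # group means within the followed-up cohort)
    has_fc = has_status | (rng.random(n) < config.calprotectin_fraction)

    # --- noisy clinical composites ------------------------------------
    partial = np.clip(np.rint(2.2 * severity + rng.normal(0, 1.2, size=n)), 0, 9)
    pga = np.clip(np.rint(0.9 * severity + rng.normal(0, 0.5, size=n)), 0, 3)
    center = rng.choice(["Edmonton", "LosAngeles"], size=n, p=[0.8, 0.2])

    samples = pd.DataFrame(index=pd.Index(sample_ids, name="sample_id"))
    samples["patient_id"] = ["P" + s for s in sample_ids]
    samples["diagnosis"] = (
        ["UC"] * len(uc_ids) + ["IBDU"] * len(ibdu_ids) + ["control"] * len(ctrl_ids)
    )
    is_ctrl = samples["diagnosis"] == "control"
    samples["endoscopic_mayo"] = np.concatenate(
        [mayo.astype(float), np.full(config.n_controls, np.nan)]
    )
    samples["partial_mayo"] = np.where(is_ctrl, np.nan, partial)
    samples["total_mayo"] = np.clip(
        samples["partial_mayo"] + samples["endoscopic_mayo"], 0, 12
    )
    samples["pga"] = np.where(is_ctrl, np.nan, pga)
    samples["fecal_calprotectin"] = np.where(
        is_ctrl | ~has_fc, np.nan, np.round(fecal_calpro, 1)
    )
    samples["labeling_kit"] = np.where(in_kit_b, "kit_B", "kit_A")
    samples["center"] = center
    samples["status_code"] = np.where(is_ctrl | ~has_status, np.nan, status.astype(float))

    matrix = pd.DataFrame(values, index=pd.Index(probe_ids, name="probe_id"),
                          columns=sample_ids)

    annotation = _make_annotation(rng, probe_ids, signal_idx, s100a8_probe, s100a9_probe)

    bundle = CohortBundle(matrix=matrix, samples=samples, annotation=annotation)
    truth = TruthTable(
        signal_probesets=[probe_ids[i] for i in signal_idx],
        effects={probe_ids[i]: float(effects[i]) for i in signal_idx},
        severity={sid: float(sv) for sid, sv in zip(sample_ids, severity)},
        kit_offsets={pid: float(o) for pid, o in zip(probe_ids, kit_offsets)},
        s100a8_probe=s100a8_probe,
        s100a9_probe=s100a9_probe,
    )
    return bundle, truth


def _make_annotation(rng, probe_ids, signal_idx, s100a8_probe, s100a9_probe) -> pd.DataFrame:
    """Probe -> gene map with several probes per gene, plus interest flags."""
    p = len(probe_ids)
    n_genes = max(2, int(round(0.4 * p)))
    gene_pool = [f"GENE{i + 1:05d}" for i in range(n_genes)]
    symbols = rng.choice(gene_pool, size=p).astype(object)

    flags = np.full(p, "", dtype=object)
    for flag in INTEREST_FLAGS:
        chosen = rng.choice(p, size=min(10, p), replace=False)
        for i in chosen:
            flags[i] = flag if flags[i] == "" else flags[i] + ";" + flag

    annotation = pd.DataFrame(
        {"gene_symbol": symbols, "flags": flags},
        index=pd.Index(probe_ids, name="probe_id"),
    )
    annotation.loc[s100a8_probe, "gene_symbol"] = "S100A8"
    annotation.loc[s100a9_probe, "gene_symbol"] = "S100A9"
    for pid in (s100a8_probe, s100a9_probe):
        old = annotation.loc[pid, "flags"]
        annotation.loc[pid, "flags"] = "calprotectin" if old == "" else old + ";calprotectin"
    return annotation


def write_cohort_files(bundle: CohortBundle, truth: TruthTable, outdir) -> dict[str, Path]:
    """Write matrix TSV, samples CSV, annotation CSV and the truth sidecar."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "matrix": outdir / "matrix.tsv",
        "samples": outdir / "samples.csv",
        "annotation": outdir / "annotation.csv",
        "truth": outdir / "truth.json",
    }
    bundle.matrix.rename_axis("probe_id").to_csv(paths["matrix"], sep="\t")
    bundle.samples.rename_axis("sample_id").to_csv(paths["samples"])
    bundle.annotation.rename_axis("probe_id").to_csv(paths["annotation"])
    truth.to_json(paths["truth"])
    return paths


def write_synthetic_gene_sets(
    truth: TruthTable,
    annotation: pd.DataFrame,
    path,
    n_random_sets: int = 20,
    set_size_range: tuple[int, int] = (10, 60),
    seed: int = 0,
) -> Path:
    """Write a synthetic GMT: one set of planted-up genes plus random sets.

    A stand-in for curated GO/KEGG collections, used because term databases
    are versioned external inputs; the planted set gives enrichment tests a
    known positive.
    """
    rng = np.random.default_rng(seed)
    universe = sorted(set(annotation["gene_symbol"]) - {""})
    up_probes = [pid for pid, eff in truth.effects.items() if eff > 0]
    planted_genes = sorted(set(annotation.loc[up_probes, "gene_symbol"]) - {""})

    lines = ["PLANTED_ACTIVITY_UP\tsynthetic planted up-regulated genes\t"
             + "\t".join(planted_genes)]
    lo, hi = set_size_range
    for i in range(n_random_sets):
        size = int(rng.integers(lo, hi + 1))
        members = rng.choice(universe, size=min(size, len(universe)), replace=False)
        lines.append(f"RANDOM_SET_{i + 1:02d}\tsynthetic random set\t" + "\t".join(sorted(members)))
    path = Path(path)
    path.write_text("\n".join(lines) + "\n")
    return path
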