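"""Control-standardized transcript-set scores, including MCalpro.

A transcript set is any user-chosen list of probe sets.  Expression is
standardized against the control population: per probe, the linear-scale
fold over the control geometric mean, 2^(x_gs - mean_controls(x_g)).  The
set score per sample is the geometric mean of the standardized values
across the set's probes, so the score lives on a positive fold-vs-control
scale and the control population itself averages (geometrically) to 1.

MCalpro — the molecular calprotectin score — is the set score over all
probes annotated to S100A8 and S100A9, whose products form the calprotectin
heterodimer measured by the stool assay.

A z-score standardization variant is available for sensitivity analysis;
note its arithmetic can produce non-positive values, which is why the
fold-of-control convention is the default.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd


@dataclass
class TranscriptSet:
    name: str
    probes: list[str]

    def __post_init__(self) -> None:
        if len(self.probes) < 1:
            raise ValueError(f"transcript set {self.name!r} is empty")


def standardize_to_controls(matrix: pd.DataFrame, control_ids,
                            method: str = "fold") -> pd.DataFrame:
    """Standardize each probe against the control population.

    ``fold`` (default): 2^(x - control mean), the linear fold over the
    control geometric mean.  ``zscore``: (x - control mean) / control SD,
    kept on the log2 scale.
    """
    control_ids = list(control_ids)
    if len(control_ids) < 2:
        raise ValueError(f"need >= 2 control samples, got {len(control_ids)}")
    missing = [c for c in control_ids if c not in matrix.columns]
    if missing:
        raise ValueError(f"control ids absent from matrix: {missing}")
    control_mean = matrix[control_ids].mean(axis=1)
    centered = matrix.sub(control_mean, axis=0)
    if method == "fold":
        return 2.0 ** centered
    if method == "zscore":
        control_sd = matrix[control_ids].std(axis=1, ddof=1)
        return centered.div(control_sd, axis=0)
    raise ValueError(f"unknown standardization method {method!r}")


def transcript_set_score(standardized: pd.DataFrame, transcript_set: TranscriptSet) -> pd.Series:
    """Geometric mean of standardized values across the set's probes."""
    missing = [p for p in transcript_set.probes if p not in standardized.index]
    if missing:
        raise KeyError(f"set {transcript_set.name!r} probes absent from matrix: {missing}")
    block = standardized.loc[transcript_set.probes].to_numpy(dtype=float)
    if np.any(block <= 0):
        raise ValueError(
            f"set {transcript_set.name!r}: geometric mean needs positive standardized "
            "values (use the fold-of-control standardization)"
        )
    scores = np.exp(np.log(block).mean(axis=0))
    return pd.Series(scores, index=standardized.columns, name=transcript_set.name)


def score_sets(matrix: pd.DataFrame, control_ids,
               transcript_sets: list[TranscriptSet]) -> pd.DataFrame:
    """Score several transcript sets at once; columns are set names."""
    standardized = standardize_to_controls(matrix, control_ids)
    return pd.DataFrame({ts.name: transcript_set_score(standardized, ts)
                         for ts in transcript_sets})


def calprotectin_set(annotation: pd.DataFrame) -> TranscriptSet:
    """All probes annotated to S100A8 or S100A9 (every probe per gene enters)."""
    probes = list(annotation.index[annotation["gene_symbol"].isin(["S100A8", "S100A9"])])
    if not probes:
        raise ValueError("annotation contains no S100A8/S100A9 probes")
    return TranscriptSet(name="MCalpro", probes=probes)


def mcalpro(matrix: pd.DataFrame, control_ids, annotation: pd.DataFrame) -> pd.Series:
    """The molecular calprotectin score per sample."""
    standardized = standardize_to_controls(matrix, control_ids)
    return transcript_set_score(standardized, calprotectin_set(annotation))


def read_transcript_sets(path) -> list[TranscriptSet]:
    """Read set definitions from a two-column CSV (set name, probe id)."""
    table = pd.read_csv(path, dtype=str)
    if table.shape[1] < 2:
        raise ValueError("transcript-set CSV needs two columns: set name, probe id")
    name_col, probe_col = table.columns[:2]
    return [TranscriptSet(name=name, probes=group[probe_col].tolist())
            for name, group in table.groupby(name_col, sort=True)]
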