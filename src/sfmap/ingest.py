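"""Reporter-ion ingestion: spectrum normalization, PSM aggregation, replicate merge.

The quantitative unit is a 10-channel isobaric reporter vector per peptide-
spectrum match (PSM), one channel per merged gradient fraction. Each spectrum
is expressed as a ratio to its reporter sum (compositional, sum-to-one), a
protein's per-replicate profile is the channel-wise median of its normalized
PSMs (renormalized, since channel medians of compositions need not sum to
one), and only proteins quantified in BOTH biological replicates enter the
merged 20-dimensional dataset used for mapping and classification.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import PipelineError, SpectrumRejected
from .markers import normalize_id

logger = logging.getLogger(__name__)

N_CHANNELS = 10
REPLICATES = ("rep1", "rep2")
REPORTER_COLS = [f"reporter_{i:02d}" for i in range(1, N_CHANNELS + 1)]
CHANNEL_COLS = [f"channel_{i:02d}" for i in range(1, N_CHANNELS + 1)]
#: Column layout of the merged profile table: rep1 block then rep2 block.
PROFILE_COLS = [
    f"{rep}_ch{i:02d}" for rep in REPLICATES for i in range(1, N_CHANNELS + 1)
]


def _sep_for(path: Path) -> str:
    return "\t" if path.suffix.lower() in {".tsv", ".txt"} else ","


def normalize_spectrum(reporters: np.ndarray) -> np.ndarray:
    """Express one reporter vector as a ratio to its sum.

    Raises :class:`SpectrumRejected` for vectors that are not quantifiable
    (wrong length, non-finite or negative entries, or zero total); callers
    at the table level catch and log these rather than aborting.
    """
    reporters = np.asarray(reporters, dtype=float)
    if reporters.shape != (N_CHANNELS,):
        raise SpectrumRejected(
            f"expected {N_CHANNELS} reporter channels, got shape {reporters.shape}"
        )
    if not np.all(np.isfinite(reporters)):
        raise SpectrumRejected("non-finite reporter value")
    if np.any(reporters < 0):
        raise SpectrumRejected("negative reporter value")
    total = reporters.sum()
    if total <= 0:
        raise SpectrumRejected("all-zero reporter vector")
    return reporters / total


def aggregate_protein(psm_reporters: np.ndarray, renormalize: bool = True) -> np.ndarray:
    """Aggregate one protein's PSMs (one replicate) to a single profile.

    Each PSM is normalized to its reporter sum first, the channel-wise
    median is taken, and the median vector is renormalized to sum one
    (switchable, default on). Input rows failing the quantifiability filter
    must already have been removed.
    """
    psm_reporters = np.atleast_2d(np.asarray(psm_reporters, dtype=float))
    if psm_reporters.shape[0] == 0:
        raise ValueError("aggregate_protein requires at least one accepted PSM")
    normalized = np.stack([normalize_spectrum(row) for row in psm_reporters])
    profile = np.median(normalized, axis=0)
    if renormalize:
        profile = profile / profile.sum()
    return profile


def read_psm_table(path: str | Path) -> pd.DataFrame:
    """Read a delimited PSM table (columns: protein_group_id, replicate, reporter_01..10)."""
    path = Path(path)
    df = pd.read_csv(path, sep=_sep_for(path))
    required = {"protein_group_id", "replicate", *REPORTER_COLS}
    missing = required - set(df.columns)
    if missing:
        raise PipelineError(f"PSM table missing columns: {sorted(missing)}")
    bad_reps = set(df["replicate"].unique()) - set(REPLICATES)
    if bad_reps:
        raise PipelineError(
            f"unsupported replicate label(s) {sorted(map(str, bad_reps))}; "
            f"the design is fixed to {REPLICATES}"
        )
    df["protein_group_id"] = df["protein_group_id"].map(normalize_id)
    return df


def aggregate_replicate(
    psm_df: pd.DataFrame, replicate: str, renormalize: bool = True
) -> pd.DataFrame:
    """Aggregate PSMs of one replicate into per-protein profiles.

    Returns a DataFrame indexed by protein_id with columns channel_01..10
    plus n_psms. Unquantifiable spectra are dropped with a logged reason;
    proteins with zero accepted PSMs are simply absent.
    """
    sub = psm_df[psm_df["replicate"] == replicate]
    rows: dict[str, np.ndarray] = {}
    n_psms: dict[str, int] = {}
    n_rejected = 0
    for pid, grp in sub.groupby("protein_group_id", sort=True):
        accepted = []
        for _, row in grp[REPORTER_COLS].iterrows():
            try:
                accepted.append(normalize_spectrum(row.to_numpy(dtype=float)))
            except SpectrumRejected as exc:
                n_rejected += 1
                logger.info("rejected PSM for %s (%s): %s", pid, replicate, exc)
        if not accepted:
            logger.info("protein %s has no quantifiable PSM in %s", pid, replicate)
            continue
        profile = np.median(np.stack(accepted), axis=0)
        if renormalize:
            profile = profile / profile.sum()
        rows[pid] = profile
        n_psms[pid] = len(accepted)
    if n_rejected:
        logger.warning("%s: rejected %d unquantifiable PSM(s)", replicate, n_rejected)
    out = pd.DataFrame.from_dict(rows, orient="index", columns=CHANNEL_COLS)
    out.index.name = "protein_id"
    out["n_psms"] = pd.Series(n_psms)
    return out.sort_index()


def merge_replicates(
    profiles_rep1: pd.DataFrame, profiles_rep2: pd.DataFrame
) -> tuple[pd.DataFrame, list[str]]:
    """Keep only proteins quantified in both replicates; concatenate profiles.

    Returns the merged table (index protein_id; columns rep1_ch01..rep2_ch10,
    n_psms_rep1, n_psms_rep2) and the sorted list of dropped single-replicate
    proteins. An empty intersection aborts the pipeline.
    """
    ids1, ids2 = set(profiles_rep1.index), set(profiles_rep2.index)
    shared = sorted(ids1 & ids2)
    dropped = sorted(ids1 ^ ids2)
    if not shared:
        raise PipelineError("no protein was quantified in both replicates")
    block1 = profiles_rep1.loc[shared, CHANNEL_COLS].to_numpy()
    block2 = profiles_rep2.loc[shared, CHANNEL_COLS].to_numpy()
    merged = pd.DataFrame(
        np.hstack([block1, block2]), index=pd.Index(shared, name="protein_id"),
        columns=PROFILE_COLS,
    )
    if "n_psms" in profiles_rep1.columns:
        merged["n_psms_rep1"] = profiles_rep1.loc[shared, "n_psms"]
        merged["n_psms_rep2"] = profiles_rep2.loc[shared, "n_psms"]
    if dropped:
        logger.warning(
            "dropped %d protein(s) present in only one replicate", len(dropped)
        )
    return merged, dropped


def build_profiles(
    psm_df: pd.DataFrame, renormalize: bool = True
) -> tuple[pd.DataFrame, list[str]]:
    """PSM table → merged both-replicate profile table (and dropped IDs)."""
    per_rep = {
        rep: aggregate_replicate(psm_df, rep, renormalize=renormalize)
        for rep in REPLICATES
    }
    return merge_replicates(per_rep["rep1"], per_rep["rep2"])


def profile_matrix(profiles: pd.DataFrame) -> np.ndarray:
    """The 20-dimensional combined profile matrix (rep1 block ∥ rep2 block)."""
    return profiles[PROFILE_COLS].to_numpy(dtype=float)


def read_profile_table(
    path: str | Path, pre_normalized: bool = False
) -> tuple[pd.DataFrame, list[str]]:
    """Alternative entry point: per-replicate protein-level quantitation.

    Expected columns: protein_id, replicate, channel_01..channel_10 (one row
    per protein per replicate; raw values unless ``pre_normalized``). Rows
    are normalized to sum one per replicate block and merged under the
    both-replicates rule.
    """
    path = Path(path)
    df = pd.read_csv(path, sep=_sep_for(path))
    required = {"protein_id", "replicate", *CHANNEL_COLS}
    missing = required - set(df.columns)
    if missing:
        raise PipelineError(f"profile table missing columns: {sorted(missing)}")
    df["protein_id"] = df["protein_id"].map(normalize_id)
    per_rep = {}
    for rep in REPLICATES:
        sub = df[df["replicate"] == rep].set_index("protein_id")[CHANNEL_COLS]
        if sub.index.has_duplicates:
            raise PipelineError(f"duplicate protein rows in replicate {rep}")
        values = sub.to_numpy(dtype=float)
        if not pre_normalized:
            totals = values.sum(axis=1, keepdims=True)
            if np.any(totals <= 0):
                raise PipelineError(f"non-positive profile total in {rep}")
            values = values / totals
        per_rep[rep] = pd.DataFrame(values, index=sub.index, columns=CHANNEL_COLS)
    return merge_replicates(per_rep["rep1"], per_rep["rep2"])


def write_profile_table(profiles: pd.DataFrame, path: str | Path) -> None:
    """Write the merged profile table; full float precision for round-tripping."""
    profiles.to_csv(Path(path), sep=_sep_for(Path(path)))


def read_merged_profiles(path: str | Path) -> pd.DataFrame:
    """Read back a table written by :func:`write_profile_table`."""
    path = Path(path)
    return pd.read_csv(path, sep=_sep_for(path), index_col="protein_id")
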