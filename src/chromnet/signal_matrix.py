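"""Promoter-level signal matrices: window counting, input-control
normalization, promoter filtering and the log/z transform.

The container is a thin wrapper around a pandas DataFrame (promoters as
rows, tracks as columns) carrying per-track roles (histone modification,
chromatin modifier, input control, expression) and a processing-state flag
that enforces pipeline order: raw counts are filtered, then normalized
against the input control, then log-transformed and standardized.

Normalization follows the median-ratio scheme: with sample counts ``S`` and
input counts ``C`` per promoter, the per-promoter enrichment ratio is
``(S + 1) / (C + 1)`` and the track-level scale ``m`` is the median of that
ratio over promoters; normalized signal is the ratio divided by ``m``.
Counts strongly tracking the input control are thereby shrunk toward one.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from .errors import (
    DataError,
    DegenerateTrackError,
    ParameterError,
    SchemaError,
    StateError,
)

logger = logging.getLogger(__name__)

# Track roles
ROLE_HM = "HM"
ROLE_CM = "CM"
ROLE_INPUT = "input"
ROLE_EXPRESSION = "expression"
VALID_ROLES = frozenset({ROLE_HM, ROLE_CM, ROLE_INPUT, ROLE_EXPRESSION})

# Processing states
STATE_RAW = "raw_counts"
STATE_NORMALIZED = "normalized"
STATE_STANDARDIZED = "standardized"

#: half-width of the promoter window around the TSS (bp)
TSS_HALF_WINDOW = 2000

#: pseudo-count added to expression tracks (which may be zero) before the
#: log transform; ChIP tracks are strictly positive after normalization and
#: get no pseudo-count.
EXPRESSION_LOG_PSEUDOCOUNT = 1.0


@dataclass(frozen=True)
class GenomicWindow:
    """A promoter window: 0-based half-open interval around a TSS."""

    chrom: str
    start: int
    end: int
    strand: str = "."
    gene_id: str = ""

    def __post_init__(self) -> None:
        if self.start < 0 or self.end <= self.start:
            raise ParameterError(
                f"invalid window {self.chrom}:{self.start}-{self.end}"
            )
        if self.strand not in {"+", "-", "."}:
            raise ParameterError(f"invalid strand {self.strand!r}")


@dataclass
class SignalMatrix:
    """Promoters x tracks signal matrix with role metadata and a state flag.

    Parameters
    ----------
    data : DataFrame
        Rows are promoters, columns are tracks.
    roles : mapping
        Track name -> one of ``HM``, ``CM``, ``input``, ``expression``.
    state : str
        One of ``raw_counts``, ``normalized``, ``standardized``.
    norm_factors : mapping
        Track -> median ratio ``m``; present once normalized.
    latent : DataFrame or None
        Synthetic-data generators may attach the latent log-signals here so
        tests can use them as oracles. Never populated for real data.
    """

    data: pd.DataFrame
    roles: dict[str, str]
    state: str = STATE_RAW
    norm_factors: dict[str, float] = field(default_factory=dict)
    latent: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        missing = set(self.data.columns) - set(self.roles)
        if missing:
            raise SchemaError(f"tracks without a role: {sorted(missing)}")
        bad = {r for r in self.roles.values() if r not in VALID_ROLES}
        if bad:
            raise SchemaError(f"unknown roles: {sorted(bad)}")
        if self.state == STATE_RAW:
            inputs = self.tracks_with_role(ROLE_INPUT)
            if len(inputs) != 1:
                raise SchemaError(
                    f"raw count matrix needs exactly one input track, got {inputs}"
                )
        if self.data.isna().any().any():
            raise SchemaError("signal matrix contains missing values")

    # -- conveniences -----------------------------------------------------

    @property
    def promoter_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def track_names(self) -> list[str]:
        return list(self.data.columns)

    def tracks_with_role(self, role: str) -> list[str]:
        return [t for t in self.data.columns if self.roles.get(t) == role]

    @property
    def hm_tracks(self) -> list[str]:
        return self.tracks_with_role(ROLE_HM)

    @property
    def cm_tracks(self) -> list[str]:
        return self.tracks_with_role(ROLE_CM)

    @property
    def chip_tracks(self) -> list[str]:
        return [
            t
            for t in self.data.columns
            if self.roles[t] in (ROLE_HM, ROLE_CM)
        ]

    @property
    def input_track(self) -> str:
        inputs = self.tracks_with_role(ROLE_INPUT)
        if len(inputs) != 1:
            raise SchemaError(f"expected one input track, found {inputs}")
        return inputs[0]

    def _require_state(self, state: str, op: str) -> None:
        if self.state != state:
            raise StateError(
                f"{op} requires state {state!r}, matrix is {self.state!r}"
            )

    # -- I/O --------------------------------------------------------------

    def to_tsv(self, matrix_path: str | Path, roles_path: str | Path) -> None:
        """Write the matrix as TSV plus a YAML sidecar with roles/state."""
        out = self.data.copy()
        out.index.name = "promoter_id"
        out.to_csv(matrix_path, sep="\t", float_format="%.17g")
        sidecar = {
            "roles": dict(self.roles),
            "state": self.state,
            "norm_factors": {k: float(v) for k, v in self.norm_factors.items()},
        }
        Path(roles_path).write_text(yaml.safe_dump(sidecar, sort_keys=True))


def read_signal_matrix(
    matrix_path: str | Path, roles_path: str | Path
) -> SignalMatrix:
    """Read a TSV matrix and its YAML role sidecar written by ``to_tsv``."""
    data = pd.read_csv(matrix_path, sep="\t", index_col=0)
    data.index = data.index.astype(str)
    sidecar = yaml.safe_load(Path(roles_path).read_text())
    return SignalMatrix(
        data=data,
        roles=dict(sidecar["roles"]),
        state=sidecar.get("state", STATE_RAW),
        norm_factors=dict(sidecar.get("norm_factors", {})),
    )


def read_bed_windows(path: str | Path) -> list[GenomicWindow]:
    """Read promoter windows from a BED file (BED4+ name column = gene id)."""
    windows = []
    for line in Path(path).read_text().splitlines():
        if not line.strip() or line.startswith(("#", "track", "browser")):
            continue
        parts = line.split("\t")
        chrom, start, end = parts[0], int(parts[1]), int(parts[2])
        gene_id = parts[3] if len(parts) > 3 else ""
        strand = parts[5] if len(parts) > 5 else "."
        windows.append(GenomicWindow(chrom, start, end, strand, gene_id))
    return windows


def write_bed_windows(windows: Sequence[GenomicWindow], path: str | Path) -> None:
    lines = [
        f"{w.chrom}\t{w.start}\t{w.end}\t{w.gene_id}\t0\t{w.strand}"
        for w in windows
    ]
    Path(path).write_text("\n".join(lines) + ("\n" if lines else ""))


# -- operations ----------------------------------------------------------


def count_reads_in_windows(
    read_positions: Mapping[str, Iterable[tuple[str, int]]],
    windows: Sequence[GenomicWindow],
    roles: Mapping[str, str],
) -> SignalMatrix:
    """Count reads (single 5' positions) in promoter windows.

    A read at position ``p`` is assigned to every window with
    ``start <= p < end`` (overlapping windows each count it). Strand is
    ignored: windows are symmetric around the TSS. Reads on chromosomes
    not covered by any window contribute nothing; a warning is logged.
    """
    if not windows:
        raise ParameterError("no windows given")
    window_ids = [w.gene_id or f"{w.chrom}:{w.start}-{w.end}" for w in windows]
    chrom_set = {w.chrom for w in windows}
    by_chrom: dict[str, list[int]] = {}
    for i, w in enumerate(windows):
        by_chrom.setdefault(w.chrom, []).append(i)

    counts = np.zeros((len(windows), len(read_positions)), dtype=np.int64)
    track_names = list(read_positions)
    for t_idx, track in enumerate(track_names):
        unknown = 0
        pos_by_chrom: dict[str, list[int]] = {}
        for chrom, pos in read_positions[track]:
            if chrom not in chrom_set:
                unknown += 1
                continue
            pos_by_chrom.setdefault(chrom, []).append(pos)
        if unknown:
            logger.warning(
                "track %s: %d reads on chromosomes without windows (counted as 0)",
                track,
                unknown,
            )
        for chrom, pos_list in pos_by_chrom.items():
            pos = np.sort(np.asarray(pos_list, dtype=np.int64))
            for w_idx in by_chrom[chrom]:
                w = windows[w_idx]
                lo = np.searchsorted(pos, w.start, side="left")
                hi = np.searchsorted(pos, w.end, side="left")
                counts[w_idx, t_idx] = hi - lo

    data = pd.DataFrame(counts, index=window_ids, columns=track_names)
    return SignalMatrix(data=data, roles=dict(roles), state=STATE_RAW)


def filter_promoters(matrix: SignalMatrix) -> SignalMatrix:
    """Keep promoters where at least one ChIP sample exceeds the input.

    A promoter is retained iff some HM or CM track has a strictly larger
    raw count than the input-control count at that promoter. Expression
    tracks do not participate (the enrichment comparison is between ChIP
    samples and their input control). Idempotent; order preserved.
    """
    matrix._require_state(STATE_RAW, "filter_promoters")
    chip = matrix.chip_tracks
    if not chip:
        raise SchemaError("no HM or CM tracks to filter on")
    input_counts = matrix.data[matrix.input_track].to_numpy()
    sample = matrix.data[chip].to_numpy()
    keep = (sample > input_counts[:, None]).any(axis=1)
    return replace(
        matrix,
        data=matrix.data.loc[keep].copy(),
        latent=matrix.latent.loc[keep].copy() if matrix.latent is not None else None,
    )


def median_ratio_normalize(matrix: SignalMatrix) -> SignalMatrix:
    """Input-control normalization of ChIP tracks by the median ratio.

    For each HM/CM track with counts S and input counts C, per promoter
    r_i = (S_i + 1) / (C_i + 1); m = median_i(r_i); output = r_i / m.
    The input track is dropped from the output; expression tracks pass
    through unchanged (they have no input control) and get no entry in
    ``norm_factors``.
    """
    matrix._require_state(STATE_RAW, "median_ratio_normalize")
    if len(matrix.data) == 0:
        raise ParameterError("cannot normalize a matrix with zero promoters")
    input_track = matrix.input_track
    c = matrix.data[input_track].to_numpy(dtype=float)
    out = {}
    norm_factors: dict[str, float] = {}
    for track in matrix.track_names:
        role = matrix.roles[track]
        if role == ROLE_INPUT:
            continue
        if role == ROLE_EXPRESSION:
            out[track] = matrix.data[track].to_numpy(dtype=float)
            continue
        s = matrix.data[track].to_numpy(dtype=float)
        ratio = (s + 1.0) / (c + 1.0)
        m = float(np.median(ratio))
        norm_factors[track] = m
        out[track] = ratio / m
    data = pd.DataFrame(out, index=matrix.data.index)
    roles = {t: matrix.roles[t] for t in data.columns}
    return SignalMatrix(
        data=data,
        roles=roles,
        state=STATE_NORMALIZED,
        norm_factors=norm_factors,
        latent=matrix.latent,
    )


def average_replicates(
    matrix: SignalMatrix, replicate_groups: Mapping[str, Sequence[str]]
) -> SignalMatrix:
    """Replace each replicate group by its per-promoter arithmetic mean.

    Group members must share a role; a track may belong to at most one
    group. The averaged track takes the group name and the shared role.
    """
    seen: dict[str, str] = {}
    for group, tracks in replicate_groups.items():
        if not tracks:
            raise ParameterError(f"replicate group {group!r} is empty")
        for t in tracks:
            if t not in matrix.roles:
                raise SchemaError(f"replicate track {t!r} not in matrix")
            if t in seen:
                raise ParameterError(
                    f"track {t!r} appears in groups {seen[t]!r} and {group!r}"
                )
            seen[t] = group
        roles = {matrix.roles[t] for t in tracks}
        if len(roles) != 1:
            raise ParameterError(
                f"replicate group {group!r} mixes roles {sorted(roles)}"
            )

    grouped = set(seen)
    out = {}
    roles_out = {}
    for track in matrix.track_names:
        if track not in grouped:
            out[track] = matrix.data[track]
            roles_out[track] = matrix.roles[track]
    for group, tracks in replicate_groups.items():
        out[group] = matrix.data[list(tracks)].mean(axis=1)
        roles_out[group] = matrix.roles[tracks[0]]
    data = pd.DataFrame(out, index=matrix.data.index)
    return replace(matrix, data=data, roles=roles_out)


def log_standardize(
    matrix: SignalMatrix,
    expression_pseudocount: float = EXPRESSION_LOG_PSEUDOCOUNT,
) -> SignalMatrix:
    """Log-transform then z-score each track.

    ChIP tracks are strictly positive after median-ratio normalization and
    are logged directly; expression tracks (averaged tag counts, possibly
    zero) get ``expression_pseudocount`` added first. Each column is then
    centered and scaled to unit standard deviation (n-1 denominator). A
    constant column cannot be standardized and raises.
    """
    matrix._require_state(STATE_NORMALIZED, "log_standardize")
    out = {}
    for track in matrix.track_names:
        x = matrix.data[track].to_numpy(dtype=float)
        if matrix.roles[track] == ROLE_EXPRESSION:
            x = x + expression_pseudocount
        if np.any(x <= 0):
            raise DataError(
                f"track {track!r} has non-positive values at the log step"
            )
        logged = np.log(x)
        sd = float(np.std(logged, ddof=1))
        if sd == 0.0 or not np.isfinite(sd):
            raise DegenerateTrackError(
                f"track {track!r} is constant after the log transform"
            )
        out[track] = (logged - logged.mean()) / sd
    data = pd.DataFrame(out, index=matrix.data.index)
    return replace(matrix, data=data, state=STATE_STANDARDIZED)
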