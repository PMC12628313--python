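"""End-to-end orchestration: simulate -> preprocess -> decode -> infer.

Convenience wrappers gluing the stage modules together for cohort-level
runs. Epoch tensors are reduced to binned features one participant at a
time, so memory stays bounded even for large cohorts.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .bayes import BayesConfig, BFSeries, run_group_inference
from .core import DesignConfig, SessionLog, match_winner
from .decode import (
    DecoderConfig,
    DecodingCurve,
    StreamKind,
    decode_timecourse,
    stream_labels,
)
from .preprocess import (
    BinnedFeatures,
    EpochTensor,
    Phase,
    baseline_correct,
    bin_and_concat,
    interpolate_bad_channels,
    rereference_common_average,
)
from .synth import EEGGenConfig, PairRecording, PlayerPolicy, make_group, simulate_eeg

__all__ = [
    "preprocess_epochs",
    "participant_features",
    "decode_participant",
    "run_cohort",
    "CohortResult",
]


def preprocess_epochs(tensors: dict[Phase, EpochTensor]) -> BinnedFeatures:
    """Standard preprocessing chain on per-phase epochs.

    Common-average reference, bad-channel interpolation (no-op when none
    are flagged), baseline correction, then 250 ms binning and phase
    concatenation. Input tensors are already at the working sampling rate;
    call :func:`rpsdecode.preprocess.downsample` first when they are not.
    """
    processed = {}
    for phase, tensor in tensors.items():
        t = rereference_common_average(tensor)
        t = interpolate_bad_channels(t)
        t = baseline_correct(t)
        processed[phase] = t
    return bin_and_concat(
        processed[Phase.DECISION], processed[Phase.RESPONSE], processed[Phase.FEEDBACK]
    )


def participant_features(
    session: SessionLog,
    player: int,
    cfg: EEGGenConfig,
    seed: int | None = None,
) -> BinnedFeatures:
    """Simulate one participant's EEG and reduce it to decoder features."""
    return preprocess_epochs(simulate_eeg(session, player, cfg, seed=seed))


def decode_participant(
    binned: BinnedFeatures,
    session: SessionLog,
    player: int,
    streams: tuple[StreamKind, ...],
    cfg: DecoderConfig,
) -> dict[StreamKind, DecodingCurve]:
    """Decode the requested label streams for one participant."""
    out = {}
    for kind in streams:
        labels = stream_labels(session, player, kind)
        curve = decode_timecourse(binned, labels, cfg)
        out[kind] = DecodingCurve(
            accuracy=curve.accuracy,
            kind=kind,
            phase_of_bin=curve.phase_of_bin,
            participant=f"{session.pair_id}/p{player}",
        )
    return out


@dataclass(frozen=True)
class CohortResult:
    curves: list[DecodingCurve]
    roles: dict[str, int | None]  # pair_id -> winner player
    bf: dict[StreamKind, dict[str, BFSeries]]


def run_cohort(
    n_pairs: int,
    winner_cfg: EEGGenConfig,
    loser_cfg: EEGGenConfig,
    streams: tuple[StreamKind, ...],
    decoder_cfg: DecoderConfig = DecoderConfig(),
    bayes_cfg: BayesConfig = BayesConfig(),
    policy_p1: PlayerPolicy | None = None,
    policy_p2: PlayerPolicy | None = None,
    design: DesignConfig = DesignConfig(),
    seed: int = 0,
) -> CohortResult:
    """Simulate a cohort, decode every participant, and run group inference."""
    curves: list[DecodingCurve] = []
    roles: dict[str, int | None] = {}
    rng = np.random.default_rng(seed ^ 0x5EED)
    for pair in make_group(
        n_pairs, winner_cfg, loser_cfg, policy_p1, policy_p2, design, seed=seed
    ):
        roles[pair.session.pair_id] = pair.match.winner_player
        for player in (1, 2):
            binned = preprocess_epochs(pair.tensors[player])
            cfg = DecoderConfig(
                lam=decoder_cfg.lam,
                n_folds=decoder_cfg.n_folds,
                pseudo_per_fold_class=decoder_cfg.pseudo_per_fold_class,
                trials_per_pseudo=decoder_cfg.trials_per_pseudo,
                seed=int(rng.integers(2**31 - 1)),
            )
            curves.extend(
                decode_participant(binned, pair.session, player, streams, cfg).values()
            )
    bf = run_group_inference(curves, roles, bayes_cfg)
    return CohortResult(curves, roles, bf)
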