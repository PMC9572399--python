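"""Synthetic prompted-gesture session generator.

The generator emulates the statistical structure of capacitive-sleeve
recordings collected under a prompted protocol: 20 Hz sampling, 4 s gesture
holds, 3 s 'Null' transition windows, five repetitions per gesture in
randomized order, and two sessions per subject separated by a break.

Each 'Null' window is built from the three transition phases observed in
prompted collection:

(i)   a lag during which the user still holds the *previous* gesture while
      parsing the next prompt,
(ii)  a quick physical transition (the only samples whose true state is a
      transition), and
(iii) a tail during which the user already holds the *next* gesture but the
      labelling has not yet caught up.

Oracle ``true_labels`` record the previous gesture / ``'Null'`` / the next
gesture across these phases so that label-repair algorithms can be scored.

Realism choices (see docs/methods.md): during phases (i) and (iii) the hand
relaxes part-way toward a slack-hand rest posture distinct from every
prompted pose — channels drift smoothly toward the rest signature and back —
which is what makes 'Null' samples statistically distinguishable from held
gestures for a classifier, while keeping the phase-boundary channel deltas
below the noise floor so the transition detector sees only the quick
phase-(ii) ramp as outlying.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .data import GESTURES, GestureRecording, N_CHANNELS, NULL_LABEL

PRESETS = ("separable", "planted_confusion", "noisy", "arthritic")


@dataclass(frozen=True)
class GestureSignature:
    """Mean channel counts for one held gesture, plus slow in-session drift."""

    mean: np.ndarray  # (8,) counts
    within_session_drift: np.ndarray  # (8,) counts/second


@dataclass
class SubjectProfile:
    """Everything subject-specific the simulator needs.

    ``confusable_groups`` lists sets of gestures whose signatures were set
    equal (within ``confusion_eps`` counts) — the simulator's analogue of a
    user who cannot produce those gestures distinctly.
    """

    signatures: dict[str, GestureSignature]
    noise_sd: float  # counts, i.i.d. Gaussian per channel
    confusable_groups: tuple[frozenset, ...] = ()
    lag_range: tuple[float, float] = (0.5, 1.2)  # phase-(i) seconds
    ramp: float = 0.4  # phase-(ii) seconds
    relax_max: float = 0.2  # peak pull toward rest during phases (i)/(iii)
    relax_rise: float = 0.3  # seconds to reach/leave the relaxed plateau
    rest: np.ndarray | None = None  # slack-hand posture; defaults to Neutral
    intersession_offset: np.ndarray = field(
        default_factory=lambda: np.zeros(N_CHANNELS)
    )
    artifact_rate: float = 0.0  # unrequested-motion events per minute
    artifact_amplitude: float = 0.0  # counts
    artifact_duration: float = 0.5  # seconds

    def __post_init__(self) -> None:
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be nonnegative")
        if self.lag_range[1] + self.ramp >= 3.0:
            raise ValueError("lag + ramp must fit inside the 3 s transition window")
        if self.rest is None:
            self.rest = self.signatures["Neutral"].mean.copy()


@dataclass(frozen=True)
class ProtocolSpec:
    """The prompting protocol: rate, hold/transition durations, repetitions."""

    rate: float = 20.0  # Hz
    hold: float = 4.0  # seconds per gesture prompt
    transition: float = 3.0  # seconds of 'Null' between prompts
    reps: int = 5  # repetitions of each gesture
    order_seed: int | None = None  # overrides the session seed for ordering

    def __post_init__(self) -> None:
        if min(self.rate, self.hold, self.transition) <= 0:
            raise ValueError("rate, hold and transition must be positive")
        if self.reps < 2:
            raise ValueError("at least 2 repetitions are needed (batching)")


DEFAULT_PROTOCOL = ProtocolSpec()

_PLANTED_GROUPS = (
    frozenset({"Spread", "Neutral"}),
    frozenset({"Thumb Adduct", "Neutral"}),
    frozenset({"Thumb Up", "Fist"}),
)
_ARTHRITIC_GROUPS = (
    frozenset({"Thumb Up", "Fist"}),
    frozenset({"Thumb Adduct", "Neutral"}),
)


def _draw_signatures(
    rng: np.random.Generator,
    min_separation: float,
    drift_sd: float,
    gestures=GESTURES,
) -> tuple[dict[str, GestureSignature], np.ndarray]:
    """Draw per-gesture channel means plus a distinct slack-hand rest posture.

    All means (including the rest posture) keep a guaranteed pairwise
    separation.  The rest posture models the unconstrained hand between
    prompts — a different state from the actively held 'Neutral' pose.
    """
    n = len(gestures) + 1  # last row is the rest posture
    for _ in range(200):
        means = rng.uniform(300.0, 900.0, size=(n, N_CHANNELS))
        dists = np.linalg.norm(means[:, None, :] - means[None, :, :], axis=-1)
        np.fill_diagonal(dists, np.inf)
        if dists.min() >= min_separation:
            break
    else:  # pragma: no cover - vanishingly unlikely at these scales
        raise RuntimeError("could not draw separated signatures")
    drifts = rng.normal(0.0, drift_sd, size=(len(gestures), N_CHANNELS))
    sigs = {
        g: GestureSignature(mean=means[i], within_session_drift=drifts[i])
        for i, g in enumerate(gestures)
    }
    return sigs, means[-1]


def _plant_confusion(
    signatures: dict[str, GestureSignature],
    groups: tuple[frozenset, ...],
    eps: float,
    rng: np.random.Generator,
    protected=("Neutral", "Fist"),
) -> None:
    """Collapse each group's signatures onto its anchor (within eps counts).

    Drift slopes are copied from the anchor too: a user who cannot produce
    two gestures distinctly drifts identically in both, so the group stays
    confusable across the whole session.
    """
    for group in groups:
        anchors = [g for g in group if g in protected]
        anchor = anchors[0] if anchors else sorted(group)[0]
        base = signatures[anchor]
        for g in sorted(group):
            if g == anchor:
                continue
            offset = rng.normal(0.0, 1.0, N_CHANNELS)
            offset *= eps / max(np.linalg.norm(offset), 1e-12)
            signatures[g] = GestureSignature(
                mean=base.mean + offset,
                within_session_drift=base.within_session_drift.copy(),
            )


def make_profile(preset: str, seed: int) -> SubjectProfile:
    """Build a reproducible subject profile from a named preset.

    ``separable``          — distinct signatures, low noise.
    ``planted_confusion``  — three confusable gesture groups (thumb/spread
                             gestures collapse onto Neutral/Fist anchors).
    ``noisy``              — heavy channel noise and frequent artifacts.
    ``arthritic``          — two confusable groups, slow variable
                             transitions, raised noise (a user with limited
                             manual dexterity).
    """
    if preset not in PRESETS:
        raise ValueError(f"unknown preset {preset!r}; choose from {PRESETS}")
    rng = np.random.default_rng(seed)
    if preset == "separable":
        sigs, rest = _draw_signatures(rng, min_separation=250.0, drift_sd=0.03)
        return SubjectProfile(
            signatures=sigs,
            rest=rest,
            noise_sd=4.0,
            intersession_offset=rng.normal(0.0, 20.0, N_CHANNELS),
            artifact_rate=0.3,
            artifact_amplitude=100.0,
        )
    if preset == "planted_confusion":
        sigs, rest = _draw_signatures(rng, min_separation=250.0, drift_sd=0.03)
        _plant_confusion(sigs, _PLANTED_GROUPS, eps=2.0, rng=rng)
        return SubjectProfile(
            signatures=sigs,
            rest=rest,
            noise_sd=6.0,
            confusable_groups=_PLANTED_GROUPS,
            intersession_offset=rng.normal(0.0, 20.0, N_CHANNELS),
            artifact_rate=0.3,
            artifact_amplitude=100.0,
        )
    if preset == "noisy":
        sigs, rest = _draw_signatures(rng, min_separation=250.0, drift_sd=0.08)
        return SubjectProfile(
            signatures=sigs,
            rest=rest,
            noise_sd=15.0,
            intersession_offset=rng.normal(0.0, 40.0, N_CHANNELS),
            artifact_rate=2.0,
            artifact_amplitude=150.0,
        )
    # arthritic
    sigs, rest = _draw_signatures(rng, min_separation=250.0, drift_sd=0.05)
    _plant_confusion(sigs, _ARTHRITIC_GROUPS, eps=3.0, rng=rng)
    return SubjectProfile(
        signatures=sigs,
        rest=rest,
        noise_sd=10.0,
        confusable_groups=_ARTHRITIC_GROUPS,
        lag_range=(0.8, 1.9),
        ramp=0.6,
        intersession_offset=rng.normal(0.0, 30.0, N_CHANNELS),
        artifact_rate=1.0,
        artifact_amplitude=120.0,
    )


def _transition_window(
    prev_mean: np.ndarray,
    next_mean: np.ndarray,
    rest: np.ndarray,
    n: int,
    lag_n: int,
    ramp_n: int,
    relax_max: float,
    rise_n: int,
) -> tuple[np.ndarray, list[str], list[str]]:
    """Channel baselines and labels for one 'Null' window of ``n`` samples.

    The relaxation pull toward the rest posture rises over ``rise_n``
    samples at the start of phase (i), plateaus at ``relax_max`` through the
    transition, and decays over the last ``rise_n`` samples of phase (iii),
    so the window's boundary samples rejoin the held-gesture clusters with
    sub-noise channel deltas.
    """
    base = np.empty((n, N_CHANNELS))
    true: list[str] = []
    tail_n = n - lag_n - ramp_n
    rise = max(rise_n, 1)
    # phase (i): still in previous gesture, relaxing toward rest
    for k in range(lag_n):
        beta = relax_max * min(1.0, (k + 1) / rise)
        base[k] = prev_mean + beta * (rest - prev_mean)
        true.append("__PREV__")
    # phase (ii): the actual transition ramp, between the relaxed endpoints
    beta_i = relax_max * min(1.0, lag_n / rise) if lag_n else relax_max
    start = prev_mean + beta_i * (rest - prev_mean)
    end = next_mean + relax_max * (rest - next_mean)
    for k in range(ramp_n):
        s = (k + 1) / (ramp_n + 1)
        base[lag_n + k] = (1 - s) * start + s * end
        true.append(NULL_LABEL)
    # phase (iii): already in next gesture, relaxation decaying to zero
    for k in range(tail_n):
        beta = relax_max * min(1.0, (tail_n - 1 - k) / rise)
        base[lag_n + ramp_n + k] = next_mean + beta * (rest - next_mean)
        true.append("__NEXT__")
    prompts = [NULL_LABEL] * n
    return base, prompts, true


def simulate_session(
    profile: SubjectProfile,
    protocol: ProtocolSpec = DEFAULT_PROTOCOL,
    seed: int = 0,
    subject_id: str = "S0",
    session_id: str = "Data1",
    channel_offset: np.ndarray | None = None,
) -> GestureRecording:
    """Simulate one prompted session.

    The prompt sequence is a seeded random permutation of
    ``reps x gestures`` with a 'Null' window between consecutive prompts
    (the same gesture may legitimately occur twice in a row).
    """
    rng = np.random.default_rng(seed)
    rate = protocol.rate
    if profile.lag_range[1] + profile.ramp >= protocol.transition:
        raise ValueError("profile lag + ramp must fit inside the transition window")
    hold_n = int(round(protocol.hold * rate))
    trans_n = int(round(protocol.transition * rate))
    gestures = list(profile.signatures)
    order_rng = (
        np.random.default_rng(protocol.order_seed)
        if protocol.order_seed is not None
        else rng
    )
    prompts_seq = [g for g in gestures for _ in range(protocol.reps)]
    prompts_seq = [prompts_seq[i] for i in order_rng.permutation(len(prompts_seq))]

    base_rows: list[np.ndarray] = []
    prompt_out: list[str] = []
    true_out: list[str] = []
    for i, g in enumerate(prompts_seq):
        if i > 0:
            prev = prompts_seq[i - 1]
            lag = rng.uniform(*profile.lag_range)
            lag_n = int(round(lag * rate))
            ramp_n = int(round(profile.ramp * rate))
            base, prm, tru = _transition_window(
                profile.signatures[prev].mean,
                profile.signatures[g].mean,
                profile.rest,
                trans_n,
                lag_n,
                ramp_n,
                profile.relax_max,
                int(round(profile.relax_rise * rate)),
            )
            tru = [prev if t == "__PREV__" else g if t == "__NEXT__" else t for t in tru]
            base_rows.append(base)
            prompt_out.extend(prm)
            true_out.extend(tru)
        base_rows.append(np.tile(profile.signatures[g].mean, (hold_n, 1)))
        prompt_out.extend([g] * hold_n)
        true_out.extend([g] * hold_n)

    base = np.vstack(base_rows)
    n = len(base)
    times = np.arange(n) / rate

    # slow within-session drift (per-gesture slope, evaluated at sample time)
    drift = np.zeros_like(base)
    pos = 0
    for i, g in enumerate(prompts_seq):
        if i > 0:
            # transition windows inherit the mean drift of the two neighbours
            slope = 0.5 * (
                profile.signatures[prompts_seq[i - 1]].within_session_drift
                + profile.signatures[g].within_session_drift
            )
            drift[pos : pos + trans_n] = np.outer(times[pos : pos + trans_n], slope)
            pos += trans_n
        slope = profile.signatures[g].within_session_drift
        drift[pos : pos + hold_n] = np.outer(times[pos : pos + hold_n], slope)
        pos += hold_n

    channels = base + drift
    if profile.noise_sd > 0:
        channels = channels + rng.normal(0.0, profile.noise_sd, channels.shape)

    # sporadic unrequested motions: square pulses on one channel
    if profile.artifact_rate > 0 and profile.artifact_amplitude > 0:
        minutes = n / rate / 60.0
        n_events = rng.poisson(profile.artifact_rate * minutes)
        width = max(int(round(profile.artifact_duration * rate)), 1)
        for _ in range(n_events):
            start = int(rng.integers(0, max(n - width, 1)))
            ch = int(rng.integers(0, N_CHANNELS))
            sign = 1.0 if rng.random() < 0.5 else -1.0
            channels[start : start + width, ch] += sign * profile.artifact_amplitude

    if channel_offset is not None:
        channels = channels + channel_offset
    channels = np.clip(channels, 0.0, None)

    return GestureRecording(
        subject_id=subject_id,
        session_id=session_id,
        times=times,
        channels=channels,
        prompt_labels=np.array(prompt_out, dtype=object),
        true_labels=np.array(true_out, dtype=object),
    )


def simulate_subject(
    profile: SubjectProfile,
    protocol: ProtocolSpec = DEFAULT_PROTOCOL,
    seed_pair: tuple[int, int] = (0, 1),
    subject_id: str = "S0",
) -> tuple[GestureRecording, GestureRecording]:
    """Simulate the two-session protocol for one subject.

    ``Data2`` gets a fresh randomized prompt order and fresh transition lags,
    plus the profile's additive inter-session channel offset (the signature
    of sensors shifting on the arm during the break).
    """
    data1 = simulate_session(
        profile, protocol, seed=seed_pair[0], subject_id=subject_id, session_id="Data1"
    )
    data2 = simulate_session(
        profile,
        protocol,
        seed=seed_pair[1],
        subject_id=subject_id,
        session_id="Data2",
        channel_offset=profile.intersession_offset,
    )
    return data1, data2
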