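"""EEG band-amplitude analysis.

Raw multichannel recordings are re-referenced to the average of the earlobe
electrodes (A1, A2), split into task sessions, each session segmented into a
fixed number of contiguous time bins, and every bin transformed with an
unwindowed (rectangular-window) DFT.  Per-bin single-sided amplitudes are
averaged within the conventional frequency bands (delta through gamma) and
across bins, giving one mean amplitude per
(participant, condition, session, channel, band).  Session-wise change is
expressed relative to the first (tone-guided) session.

Amplitude convention: ``A_k = 2|X_k|/N`` for ``0 < k < N/2`` (DC and Nyquist
excluded), so a pure sinusoid of amplitude ``A`` at a bin frequency
contributes ``A`` at its bin.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

SCALP_CHANNELS = ("Fz", "Cz", "Pz", "Oz", "C3", "C4", "T3", "T4")
REFERENCE_CHANNELS = ("A1", "A2")
ALL_CHANNELS = SCALP_CHANNELS + REFERENCE_CHANNELS


@dataclass(frozen=True)
class BandDefinition:
    """A half-open frequency band [f_lo, f_hi) in Hz."""

    name: str
    f_lo: float
    f_hi: float

    def __post_init__(self) -> None:
        if not (0 <= self.f_lo < self.f_hi):
            raise ValueError(f"invalid band edges for {self.name!r}: "
                             f"[{self.f_lo}, {self.f_hi})")


#: Conventional EEG bands, half-open intervals in Hz.
DEFAULT_BANDS: tuple[BandDefinition, ...] = (
    BandDefinition("delta", 0.5, 4.0),
    BandDefinition("theta", 4.0, 8.0),
    BandDefinition("alpha", 8.0, 14.0),
    BandDefinition("beta", 14.0, 30.0),
    BandDefinition("gamma", 30.0, 55.0),
)

#: Electrode restriction used for band-wise inference.  Delta is used only
#: by the cohort exclusion rule and has no electrodes of interest.
_ELECTRODES_OF_INTEREST = {
    "gamma": ("Pz", "T3", "T4"),   # temporoparietal, mental state
    "beta": ("C3", "C4"),          # central, mental burden
    "alpha": ("C3", "C4"),         # central, thermal sensation
    "theta": ("Fz",),              # frontal-midline theta
}


@dataclass
class Recording:
    """A session-annotated multichannel EEG recording.

    ``samples`` is a (n_channels, n_samples) float array in microvolts, row
    order given by ``channel_labels``.  ``session_spans`` lists
    ``(session_index, start_s, end_s)`` in seconds, non-overlapping and
    ordered; session indices are 1-based.
    """

    samples: np.ndarray
    sampling_rate: float
    channel_labels: tuple[str, ...]
    session_spans: list[tuple[int, float, float]]
    participant: int | str | None = None
    condition: str | None = None
    rereferenced: bool = False
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        self.channel_labels = tuple(self.channel_labels)
        if self.samples.ndim != 2:
            raise ValueError("samples must be 2-D (channels x time)")
        if len(self.channel_labels) != self.samples.shape[0]:
            raise ValueError("channel_labels length does not match samples")
        if len(set(self.channel_labels)) != len(self.channel_labels):
            raise ValueError("duplicate channel labels")
        if self.sampling_rate <= 110.0:
            raise ValueError("sampling_rate must exceed 110 Hz "
                             "(twice the top gamma edge)")
        spans = sorted(self.session_spans, key=lambda s: s[1])
        for (_, a0, a1), (_, b0, _b1) in zip(spans, spans[1:]):
            if a1 > b0 + 1e-9:
                raise ValueError("session spans overlap")
        for _, t0, t1 in spans:
            if t1 <= t0:
                raise ValueError("empty session span")
        self.session_spans = spans

    def channel(self, label: str) -> np.ndarray:
        try:
            return self.samples[self.channel_labels.index(label)]
        except ValueError:
            raise KeyError(f"channel {label!r} not present") from None

    @property
    def sessions(self) -> list[int]:
        return [s for s, _, _ in self.session_spans]


def rereference(recording: Recording) -> Recording:
    """Re-reference every scalp channel to the average of A1 and A2.

    Returns a new recording with ``x - (A1 + A2) / 2`` on the scalp
    channels.  A1/A2 are retained unchanged but the output is flagged so a
    second application (which would change values again) is refused.
    """
    if recording.rereferenced:
        raise ValueError("recording is already re-referenced; "
                         "refusing to apply the reference twice")
    for ref in REFERENCE_CHANNELS:
        if ref not in recording.channel_labels:
            raise ValueError(f"reference channel {ref!r} missing")
    ref = 0.5 * (recording.channel("A1") + recording.channel("A2"))
    out = recording.samples.copy()
    for i, label in enumerate(recording.channel_labels):
        if label not in REFERENCE_CHANNELS:
            out[i] = out[i] - ref
    return replace(recording, samples=out, rereferenced=True)


def segment_session(recording: Recording, session: int,
                    n_bins: int = 20) -> list[np.ndarray]:
    """Split one session span into ``n_bins`` contiguous time bins.

    Returns a list of (n_channels, block_length) arrays.  Block lengths
    differ by at most one sample; the remainder goes to the earliest blocks.
    """
    if n_bins < 1:
        raise ValueError("n_bins must be >= 1")
    span = next((s for s in recording.session_spans if s[0] == session), None)
    if span is None:
        raise KeyError(f"session {session} not found")
    _, t0, t1 = span
    fs = recording.sampling_rate
    i0 = int(round(t0 * fs))
    i1 = int(round(t1 * fs))
    n = i1 - i0
    if n < n_bins:
        raise ValueError(f"session {session} has {n} samples, "
                         f"fewer than n_bins={n_bins}")
    base, rem = divmod(n, n_bins)
    blocks = []
    start = i0
    for b in range(n_bins):
        length = base + (1 if b < rem else 0)
        blocks.append(recording.samples[:, start:start + length])
        start += length
    return blocks


def band_amplitudes(block: np.ndarray, sampling_rate: float,
                    bands=DEFAULT_BANDS) -> dict[str, float]:
    """Mean single-sided DFT amplitude per band for one sample block.

    ``block`` is a 1-D sample vector (or a (channels, time) array, in which
    case a dict of per-band vectors over channels is returned).  Amplitudes
    are ``2|X_k|/N`` for interior bins ``0 < k < N/2``; a band's value is the
    unweighted mean over bins whose centre frequency ``k*fs/N`` lies in
    ``[f_lo, f_hi)``.
    """
    x = np.asarray(block, dtype=float)
    if not np.all(np.isfinite(x)):
        raise ValueError("non-finite samples in block")
    n = x.shape[-1]
    if n < 2:
        raise ValueError("block must contain at least 2 samples")
    spec = np.fft.rfft(x, axis=-1)
    k = np.arange(spec.shape[-1])
    freqs = k * sampling_rate / n
    interior = (k > 0) & (2 * k < n)  # exclude DC and (even-N) Nyquist
    amp = 2.0 * np.abs(spec) / n
    out = {}
    for band in bands:
        sel = interior & (freqs >= band.f_lo) & (freqs < band.f_hi)
        if not sel.any():
            raise ValueError(f"band {band.name!r} has no DFT bins at N={n}, "
                             f"fs={sampling_rate}")
        out[band.name] = amp[..., sel].mean(axis=-1)
    return out


def session_band_table(recording: Recording, bands=DEFAULT_BANDS,
                       n_bins: int = 20) -> pd.DataFrame:
    """Per-session mean band amplitudes for every scalp channel.

    Returns a tidy frame with columns participant, condition, session,
    channel, band, value_uV; the value is the mean over the ``n_bins``
    per-bin band amplitudes.  The recording must be re-referenced first.
    """
    if not recording.rereferenced:
        raise ValueError("recording must be re-referenced before spectral "
                         "analysis (call rereference first)")
    scalp_idx = [i for i, c in enumerate(recording.channel_labels)
                 if c not in REFERENCE_CHANNELS]
    scalp_labels = [recording.channel_labels[i] for i in scalp_idx]
    rows = []
    for session in recording.sessions:
        blocks = segment_session(recording, session, n_bins)
        # accumulate per-band means over blocks
        sums: dict[str, np.ndarray] = {}
        for block in blocks:
            amps = band_amplitudes(block[scalp_idx], recording.sampling_rate,
                                   bands)
            for name, vec in amps.items():
                sums[name] = sums.get(name, 0.0) + vec
        for name in sums:
            means = sums[name] / len(blocks)
            for ch, v in zip(scalp_labels, means):
                rows.append((recording.participant, recording.condition,
                             session, ch, name, float(v)))
    df = pd.DataFrame(rows, columns=["participant", "condition", "session",
                                     "channel", "band", "value_uV"])
    df.attrs["n_time_bins"] = n_bins
    df.attrs["window"] = "rectangular"
    return df


def differential_from_first(table: pd.DataFrame,
                            direction: str = "from_baseline") -> pd.DataFrame:
    """Amplitude change of each session relative to session 1.

    ``direction='from_baseline'`` (default) returns session − session1, the
    change from baseline; ``'baseline_minus'`` returns session1 − session.
    Session-1 rows are exactly zero either way.
    """
    if direction not in ("from_baseline", "baseline_minus"):
        raise ValueError(f"unknown direction {direction!r}")
    keys = ["participant", "condition", "channel", "band"]
    base = table[table["session"] == 1].set_index(keys)["value_uV"]
    if base.index.has_duplicates:
        raise ValueError("duplicate session-1 rows")
    groups = table.set_index(keys)
    missing = groups.index.unique().difference(base.index)
    if len(missing):
        raise ValueError(f"missing session-1 baseline for keys: "
                         f"{list(missing)[:10]}")
    out = table.copy()
    aligned = base.reindex(pd.MultiIndex.from_frame(table[keys])).to_numpy()
    if direction == "from_baseline":
        out["value_uV"] = table["value_uV"].to_numpy() - aligned
    else:
        out["value_uV"] = aligned - table["value_uV"].to_numpy()
    out.attrs = dict(table.attrs)
    out.attrs["differential"] = direction
    return out


def electrodes_of_interest(band: str) -> tuple[str, ...]:
    """Channels at which a band enters inference.

    gamma -> (Pz, T3, T4); beta and alpha -> (C3, C4); theta -> (Fz,).
    Delta is used only by the exclusion rule and raises.
    """
    try:
        return _ELECTRODES_OF_INTEREST[band]
    except KeyError:
        raise ValueError(
            f"band {band!r} has no electrodes of interest "
            "(delta enters only the exclusion rule)") from None
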