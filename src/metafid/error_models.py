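"""Platform-specific sequencing error models.

454 pyrosequencing is modelled at the flowgram level: nucleotides are
flowed in a fixed repeating order (TACG) and the light signal observed for
a homopolymer of length n is Gaussian with mean n and standard deviation
0.15*sqrt(n); flows not matching the template (negative flows) emit
low-level lognormal noise with mean 0.23 and standard deviation 0.15 (on
the natural scale of the signal).  Base calling rounds each signal to the
nearest integer, which is exactly how homopolymer over/under-calls and the
occasional negative-flow insertion arise.  Flowgrams can be serialised to
binary SFF v1, the native 454 container.

Illumina errors are dominated by substitutions whose rate grows towards
the 3' end; the per-position rate is a fourth-degree polynomial in the
relative position x in [0,1], defaulting to coefficients that give a
read-average rate of ~0.94% and ~3.6% at the final position.  Insertions
and deletions occur at a per-base rate of 1e-6 (0.0001%).
"""

from __future__ import annotations

import struct
from dataclasses import dataclass, field

import numpy as np

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)

#: substitution-rate polynomial, lowest order first: gives ~0.94% mean
#: rate over a read and 3.6% at the 3'-most position
DEFAULT_POLY_COEFFS = (0.002, 0.002, 0.0, 0.0, 0.032)


@dataclass
class FlowModel:
    """454 flow-signal model parameters."""

    flow_order: str = "TACG"
    key_sequence: str = "TCAG"
    positive_sd_coeff: float = 0.15
    negative_mean: float = 0.23
    negative_sd: float = 0.15

    def __post_init__(self) -> None:
        if sorted(self.flow_order) != sorted("ACGT"):
            raise ValueError("flow_order must be a permutation of TACG")
        if self.positive_sd_coeff < 0 or self.negative_mean <= 0 or self.negative_sd < 0:
            raise ValueError("model coefficients must be non-negative (mean > 0)")

    @property
    def lognormal_params(self) -> tuple[float, float]:
        """Underlying normal (mu, sigma) for the natural-scale mean/sd.

        The printed 0.23/0.15 are read as the mean and sd of the signal
        itself (what the instrument reports), so mu = ln(m^2/sqrt(m^2+s^2))
        and sigma^2 = ln(1 + s^2/m^2).
        """
        m, s = self.negative_mean, self.negative_sd
        mu = np.log(m * m / np.sqrt(m * m + s * s))
        sigma = np.sqrt(np.log(1.0 + (s * s) / (m * m)))
        return float(mu), float(sigma)


@dataclass
class Flowgram:
    """Ordered flow signals for one 454-style read."""

    signals: np.ndarray
    flow_order: str
    called_sequence: str = ""
    name: str = ""

    def __post_init__(self) -> None:
        self.signals = np.asarray(self.signals, dtype=float)
        if (self.signals < 0).any():
            raise ValueError("flow signals must be non-negative")


@dataclass
class IlluminaModel:
    """Position-dependent substitution profile plus a flat indel rate."""

    poly_coeffs: tuple[float, ...] = DEFAULT_POLY_COEFFS
    indel_prob: float = 1e-6

    def __post_init__(self) -> None:
        if len(self.poly_coeffs) != 5:
            raise ValueError("poly_coeffs must have 5 entries (degree 4)")
        if not 0 <= self.indel_prob <= 1:
            raise ValueError("indel_prob must be in [0, 1]")


def flow_signal_positive(
    n: int | np.ndarray, model: FlowModel, rng: np.random.Generator, size=None
) -> float | np.ndarray:
    """Signal for a matching flow over a homopolymer of length n.

    Normal(n, coeff*sqrt(n)), truncated at 0 (the truncation mass is
    negligible for the default coefficient).
    """
    n_arr = np.asarray(n)
    if (n_arr < 1).any():
        raise ValueError("homopolymer length must be >= 1")
    draw = rng.normal(n_arr, model.positive_sd_coeff * np.sqrt(n_arr), size=size)
    out = np.maximum(draw, 0.0)
    return float(out) if np.isscalar(n) and size is None else out


def flow_signal_negative(
    model: FlowModel, rng: np.random.Generator, size=None
) -> float | np.ndarray:
    """Noise signal for a non-matching flow (lognormal, natural-scale
    mean ``negative_mean`` and sd ``negative_sd``)."""
    mu, sigma = model.lognormal_params
    draw = rng.lognormal(mu, sigma, size=size)
    return float(draw) if size is None else draw


def _homopolymer_runs(seq: str) -> list[tuple[str, int]]:
    runs: list[tuple[str, int]] = []
    for ch in seq:
        if runs and runs[-1][0] == ch:
            runs[-1] = (ch, runs[-1][1] + 1)
        else:
            runs.append((ch, 1))
    return runs


def flowgram_from_sequence(
    seq: str, model: FlowModel, rng: np.random.Generator, name: str = ""
) -> Flowgram:
    """Simulate the flowgram a 454 instrument would record for ``seq``.

    The flow order cycles until the sequence is consumed; matching flows
    draw a positive signal for the whole homopolymer, non-matching flows a
    negative signal.
    """
    if not set(seq) <= set("ACGT"):
        raise ValueError("sequence must be over {A,C,G,T}")
    runs = _homopolymer_runs(seq)
    signals: list[float] = []
    i = 0
    flow_i = 0
    order = model.flow_order
    while i < len(runs):
        base = order[flow_i % len(order)]
        if runs[i][0] == base:
            signals.append(float(flow_signal_positive(runs[i][1], model, rng)))
            i += 1
        else:
            signals.append(float(flow_signal_negative(model, rng)))
        flow_i += 1
    fg = Flowgram(np.array(signals), order, name=name)
    fg.called_sequence = call_flowgram(fg)
    return fg


def call_flowgram(fg: Flowgram) -> str:
    """Base-call a flowgram: round each signal to the nearest integer
    (ties at .5 round up) and emit that many copies of the flowed base."""
    counts = np.floor(fg.signals + 0.5).astype(int)
    order = fg.flow_order
    return "".join(
        order[i % len(order)] * int(c) for i, c in enumerate(counts) if c > 0
    )


# --- SFF v1 serialisation ------------------------------------------------

_SFF_MAGIC = 0x2E736666  # ".sff"
_SFF_VERSION = b"\x00\x00\x00\x01"


def _pad8(n: int) -> int:
    return (8 - n % 8) % 8


def write_sff(flowgrams: list[Flowgram], path, key_sequence: str = "TCAG") -> None:
    """Write flowgrams as a binary SFF v1 file.

    All flowgrams must share the flow order; shorter flowgrams are padded
    with zero flows to the common flow count (the format fixes the number
    of flows per read in the common header).  Signals are quantised to
    1/100 as uint16.
    """
    if flowgrams:
        orders = {fg.flow_order for fg in flowgrams}
        if len(orders) != 1:
            raise ValueError("all flowgrams must share a flow order")
        base_order = flowgrams[0].flow_order
        n_flows = max(len(fg.signals) for fg in flowgrams)
        reps = -(-n_flows // len(base_order))
        flow_chars = (base_order * reps)[:n_flows].encode()
    else:
        flow_chars = b""
        n_flows = 0

    key = key_sequence.encode()
    header_len = 31 + n_flows + len(key)
    header_len += _pad8(header_len)
    with open(path, "wb") as fh:
        head = struct.pack(
            ">I4sQIIHHHB",
            _SFF_MAGIC,
            _SFF_VERSION,
            0,  # index_offset (no index written)
            0,  # index_length
            len(flowgrams),
            header_len,
            len(key),
            n_flows,
            1,  # flowgram_format_code: uint16 / 100
        )
        fh.write(head)
        fh.write(flow_chars)
        fh.write(key)
        fh.write(b"\x00" * _pad8(31 + n_flows + len(key)))

        for fg in flowgrams:
            called = fg.called_sequence or call_flowgram(fg)
            name = (fg.name or "read").encode()
            rh_len = 16 + len(name)
            rh_len += _pad8(16 + len(name))
            fh.write(
                struct.pack(
                    ">HHIHHHH",
                    rh_len,
                    len(name),
                    len(called),
                    0, 0, 0, 0,  # clip points: no clipping
                )
            )
            fh.write(name)
            fh.write(b"\x00" * _pad8(16 + len(name)))

            quant = np.clip(np.round(fg.signals * 100), 0, 65535).astype(">u2")
            padded = np.zeros(n_flows, dtype=">u2")
            padded[: len(quant)] = quant
            fh.write(padded.tobytes())
            # flow index per base: delta-encoded flow number of each call
            counts = np.floor(fg.signals + 0.5).astype(int)
            deltas = []
            prev = 0
            for i, c in enumerate(counts):
                for j in range(int(c)):
                    deltas.append((i + 1 - prev) if j == 0 else 0)
                    prev = i + 1
            fh.write(bytes(min(d, 255) for d in deltas))
            fh.write(called.encode())
            fh.write(bytes([40] * len(called)))  # flat quality
            data_len = 2 * n_flows + 3 * len(called)
            fh.write(b"\x00" * _pad8(data_len))


def read_sff(path) -> list[Flowgram]:
    """Read an SFF v1 file written by :func:`write_sff` (or a compatible
    producer with flowgram format code 1)."""
    with open(path, "rb") as fh:
        head = fh.read(31)
        if len(head) < 31:
            raise ValueError("truncated SFF: common header incomplete (offset 0)")
        magic, version, _ixo, _ixl, n_reads, header_len, key_len, n_flows, fmt = (
            struct.unpack(">I4sQIIHHHB", head)
        )
        if magic != _SFF_MAGIC:
            raise ValueError(f"bad SFF magic {magic:#x} at offset 0")
        if version != _SFF_VERSION or fmt != 1:
            raise ValueError("unsupported SFF version or flowgram format code")
        flow_chars = fh.read(n_flows).decode()
        _key = fh.read(key_len).decode()
        fh.seek(header_len)

        flow_order = flow_chars[:4] if n_flows >= 4 else flow_chars
        out: list[Flowgram] = []
        for _ in range(n_reads):
            rh = fh.read(16)
            if len(rh) < 16:
                raise ValueError(f"truncated SFF: read header at offset {fh.tell()}")
            rh_len, name_len, n_bases, *_clips = struct.unpack(">HHIHHHH", rh)
            name = fh.read(name_len).decode()
            fh.read(rh_len - 16 - name_len)
            signals = (
                np.frombuffer(fh.read(2 * n_flows), dtype=">u2").astype(float) / 100.0
            )
            fh.read(n_bases)  # flow index per base
            bases = fh.read(n_bases).decode()
            fh.read(n_bases)  # qualities
            fh.read(_pad8(2 * n_flows + 3 * n_bases))
            out.append(
                Flowgram(signals, flow_order, called_sequence=bases, name=name)
            )
        return out


# --- Illumina ------------------------------------------------------------

def substitution_prob(
    position: int | np.ndarray, read_length: int, model: IlluminaModel
) -> float | np.ndarray:
    """Substitution probability at a 0-based position of a read.

    The degree-4 polynomial is evaluated at x = position/(read_length-1)
    (x = 0 for length-1 reads) and clipped to [0, 1].
    """
    pos = np.asarray(position)
    if (pos < 0).any() or (pos >= read_length).any():
        raise ValueError(f"position out of range for read length {read_length}")
    x = pos / (read_length - 1) if read_length > 1 else np.zeros_like(pos, dtype=float)
    p = np.polynomial.polynomial.polyval(x, model.poly_coeffs)
    p = np.clip(p, 0.0, 1.0)
    return float(p) if np.isscalar(position) else p


def apply_illumina_errors(
    seq: str, model: IlluminaModel, rng: np.random.Generator
) -> tuple[str, list[tuple[int, str, str, str]]]:
    """Mutate one read under the Illumina model.

    Per position: substitute to a uniformly chosen *different* base with
    the position-dependent probability; independently insert (before the
    position, uniform base) or delete with ``indel_prob`` split evenly.
    Returns the mutated sequence and an error log of
    (position, type, from, to) tuples with 0-based positions in the
    original read.
    """
    if not seq:
        raise ValueError("empty sequence")
    L = len(seq)
    probs = substitution_prob(np.arange(L), L, model)
    sub_hits = rng.random(L) < probs
    indel_hits = rng.random(L) < model.indel_prob
    arr = np.frombuffer(seq.encode(), dtype=np.uint8).copy()
    log: list[tuple[int, str, str, str]] = []

    for pos in np.nonzero(sub_hits)[0]:
        old = chr(arr[pos])
        choices = [b for b in "ACGT" if b != old]
        new = choices[rng.integers(0, len(choices))]
        arr[pos] = ord(new)
        log.append((int(pos), "sub", old, new))

    out = [chr(c) for c in arr]
    for pos in sorted(np.nonzero(indel_hits)[0], reverse=True):
        pos = int(pos)
        if rng.random() < 0.5:
            ins = "ACGT"[rng.integers(0, 4)]
            out.insert(pos, ins)
            log.append((pos, "ins", "-", ins))
        else:
            log.append((pos, "del", out.pop(pos), "-"))
    log.sort(key=lambda e: e[0])
    return "".join(out), log


def count_indel_events(
    n_bases: int,
    model: IlluminaModel,
    rng: np.random.Generator,
    chunk: int = 10_000_000,
) -> int:
    """Run the per-base Bernoulli indel process over ``n_bases`` bases and
    count events (vectorised in chunks; same process as
    :func:`apply_illumina_errors`, substitutions aside)."""
    total = 0
    remaining = n_bases
    while remaining > 0:
        m = min(chunk, remaining)
        total += int((rng.random(m) < model.indel_prob).sum())
        remaining -= m
    return total


def substitution_counts_by_position(
    n_reads: int, read_length: int, model: IlluminaModel, rng: np.random.Generator
) -> np.ndarray:
    """Simulate the substitution process for ``n_reads`` reads and return
    the number of reads with a substitution at each position.

    Each position's count is the sum of independent Bernoulli trials at
    that position's rate, drawn as a binomial per position.
    """
    probs = substitution_prob(np.arange(read_length), read_length, model)
    return rng.binomial(n_reads, probs)
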