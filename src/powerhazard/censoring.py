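"""Progressive type-II censoring: schemes, samples, simulation, and file I/O.

A life test puts ``n`` units on test and observes ``m`` failures.  At the
i-th observed failure, ``R_i`` of the surviving units are withdrawn, with
``sum(R) + m = n``.  Removal positions are 1-based throughout the public
interface and the file format.

File format (the only bespoke format in this package)::

    # n=23 m=18 beta=0.332
    time,removed
    0.1788,0
    ...

Comment lines start with ``#``; the ``n=... m=...`` header comment is
required, ``beta`` is optional.  Rows are ordered by ascending failure time.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .distribution import PHFDParams, quantile, sample_iid

__all__ = [
    "CensoringScheme",
    "ProgCensSample",
    "validate_scheme",
    "build_scheme",
    "sample_progressive",
    "sample_progressive_naive",
    "read_sample",
    "write_sample",
]

logger = logging.getLogger(__name__)

SCHEME_KINDS = ("I", "II", "III")


@dataclass(frozen=True)
class CensoringScheme:
    """Design of a progressively censored life test.

    ``n`` units on test, ``removals = (R_1, ..., R_m)`` withdrawn at each of
    the ``m`` observed failures.
    """

    n: int
    removals: tuple[int, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "removals", tuple(int(r) for r in self.removals))

    @property
    def m(self) -> int:
        return len(self.removals)


@dataclass(frozen=True)
class ProgCensSample:
    """An observed progressively censored sample: the design plus the
    ordered failure times ``x_1 < ... < x_m``."""

    scheme: CensoringScheme
    times: tuple[float, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "times", tuple(float(t) for t in self.times))
        validate_scheme(self.scheme)
        if len(self.times) != self.scheme.m:
            raise ValueError(
                f"sample has {len(self.times)} times but the scheme observes "
                f"m={self.scheme.m} failures"
            )
        arr = np.asarray(self.times)
        if arr.size and arr[0] <= 0:
            raise ValueError("failure times must be strictly positive")
        if np.any(np.diff(arr) <= 0):
            raise ValueError("failure times must be strictly increasing")

    @property
    def m(self) -> int:
        return self.scheme.m

    @property
    def n(self) -> int:
        return self.scheme.n


def validate_scheme(scheme: CensoringScheme) -> CensoringScheme:
    """Check the design invariants; return the scheme unchanged if valid.

    Raises ``ValueError`` naming the violated constraint: a negative removal,
    ``m > n``, or ``sum(removals) + m != n``.
    """
    n, m, removals = scheme.n, scheme.m, scheme.removals
    if n < 1 or m < 1:
        raise ValueError(f"need n >= 1 and m >= 1, got n={n}, m={m}")
    if m > n:
        raise ValueError(f"observed failures m={m} exceed units on test n={n}")
    negative = [i + 1 for i, r in enumerate(removals) if r < 0]
    if negative:
        raise ValueError(f"negative removal count at position(s) {negative}")
    total = sum(removals) + m
    if total != n:
        raise ValueError(
            f"sum(removals) + m = {total} does not equal n = {n}"
        )
    return scheme


def build_scheme(kind: str, n: int, m: int) -> CensoringScheme:
    """Construct one of the three standard one-point removal patterns.

    * ``"I"``   — all ``n - m`` withdrawals at the first failure;
    * ``"II"``  — all at the middle failure (position ``(m+1)/2`` for odd
      ``m``, ``m/2`` for even ``m``, 1-based);
    * ``"III"`` — all at the last failure (equivalent to ordinary type-II
      right censoring).
    """
    if not 1 <= m <= n:
        raise ValueError(f"need 1 <= m <= n, got n={n}, m={m}")
    kind = str(kind).strip().upper()
    removals = [0] * m
    if kind == "I":
        pos = 1
    elif kind == "II":
        pos = (m + 1) // 2 if m % 2 else m // 2
    elif kind == "III":
        pos = m
    else:
        raise ValueError(f"unknown scheme kind {kind!r}; expected one of {SCHEME_KINDS}")
    removals[pos - 1] = n - m
    return validate_scheme(CensoringScheme(n=n, removals=tuple(removals)))


def sample_progressive(
    scheme: CensoringScheme,
    params: PHFDParams,
    seed: int | np.random.Generator | None = None,
) -> ProgCensSample:
    """Draw one sample from the exact joint law of progressively censored
    order statistics under ``scheme``.

    Uses the uniform-spacings transformation: independent uniforms are raised
    to reciprocal cumulative-weight powers, cumulatively multiplied into
    uniform progressive order statistics, then mapped through the model
    quantile function.  Deterministic under a fixed integer seed.
    """
    validate_scheme(scheme)
    rng = np.random.default_rng(seed)
    m = scheme.m
    r = np.asarray(scheme.removals, dtype=float)
    # exponent for V_i is i + R_m + R_{m-1} + ... + R_{m-i+1}, i = 1..m
    weights = np.arange(1, m + 1) + np.cumsum(r[::-1])
    for _ in range(100):
        w = rng.random(m)
        v = np.power(w, 1.0 / weights)
        u = 1.0 - np.cumprod(v[::-1])
        times = quantile(u, params)
        if np.all(np.diff(times) > 0) and times[0] > 0:
            return ProgCensSample(scheme=scheme, times=tuple(times))
        logger.debug("tied/degenerate draw (floating-point); regenerating")
    raise RuntimeError("could not draw a strictly increasing sample in 100 attempts")


def sample_progressive_naive(
    scheme: CensoringScheme,
    params: PHFDParams,
    seed: int | np.random.Generator | None = None,
) -> ProgCensSample:
    """Literal simulation of the withdrawal process.

    Generates ``n`` individual lifetimes; at the i-th observed failure the
    failed unit leaves and ``R_i`` surviving units are withdrawn uniformly at
    random.  Slower than :func:`sample_progressive`; kept as an independent
    cross-validation route for it.
    """
    validate_scheme(scheme)
    rng = np.random.default_rng(seed)
    lifetimes = sample_iid(params, scheme.n, rng)
    alive = list(range(scheme.n))
    times = []
    for r_i in scheme.removals:
        idx = min(alive, key=lambda j: lifetimes[j])
        times.append(lifetimes[idx])
        alive.remove(idx)
        if r_i:
            drop = rng.choice(len(alive), size=r_i, replace=False)
            for k in sorted(drop, reverse=True):
                alive.pop(k)
    return ProgCensSample(scheme=scheme, times=tuple(times))


def write_sample(
    sample: ProgCensSample, path: str | Path, beta: float | None = None
) -> None:
    """Write a sample in the delimited text format described in the module
    docstring.  ``beta`` is recorded in the header comment when given."""
    lines = [
        f"# n={sample.n} m={sample.m}" + (f" beta={beta!r}" if beta is not None else "")
    ]
    lines.append("time,removed")
    for t, r in zip(sample.times, sample.scheme.removals):
        lines.append(f"{t!r},{r}")
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")


def _parse_header(comments: list[str], path: Path) -> dict[str, str]:
    fields: dict[str, str] = {}
    for line in comments:
        for token in line.lstrip("#").split():
            if "=" in token:
                key, _, value = token.partition("=")
                fields[key.strip()] = value.strip()
    if "n" not in fields or "m" not in fields:
        raise ValueError(f"{path}: missing required '# n=<int> m=<int>' header comment")
    return fields


def read_sample(path: str | Path) -> ProgCensSample:
    """Read a censored sample file; validates ordering and the scheme sum."""
    sample, _ = read_sample_with_beta(path)
    return sample


def read_sample_with_beta(path: str | Path) -> tuple[ProgCensSample, float | None]:
    """As :func:`read_sample`, also returning the optional header ``beta``."""
    path = Path(path)
    comments: list[str] = []
    rows: list[tuple[float, int]] = []
    header_seen = False
    for lineno, raw in enumerate(path.read_text(encoding="utf-8").splitlines(), 1):
        line = raw.strip()
        if not line:
            continue
        if line.startswith("#"):
            comments.append(line)
            continue
        if not header_seen:
            if [c.strip().lower() for c in line.split(",")] != ["time", "removed"]:
                raise ValueError(f"{path}:{lineno}: expected header 'time,removed'")
            header_seen = True
            continue
        parts = line.split(",")
        if len(parts) != 2:
            raise ValueError(f"{path}:{lineno}: malformed row {raw!r}")
        try:
            t = float(parts[0])
            r = int(parts[1])
        except ValueError as exc:
            raise ValueError(f"{path}:{lineno}: malformed row {raw!r}") from exc
        rows.append((t, r))
    fields = _parse_header(comments, path)
    n = int(fields["n"])
    declared_m = int(fields["m"])
    if declared_m != len(rows):
        raise ValueError(
            f"{path}: header declares m={declared_m} but file has {len(rows)} rows"
        )
    times = tuple(t for t, _ in rows)
    if any(b <= a for a, b in zip(times, times[1:])):
        raise ValueError(f"{path}: failure times are not strictly increasing")
    scheme = validate_scheme(
        CensoringScheme(n=n, removals=tuple(r for _, r in rows))
    )
    beta = float(fields["beta"]) if "beta" in fields else None
    return ProgCensSample(scheme=scheme, times=times), beta
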