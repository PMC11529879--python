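"""Pixel-wise beta-value computation from user-defined channel algebra.

The beta-value is any biophysical readout expressible as arithmetic over up
to four channel intensities: the generalized polarization ``(C1-C2)/(C1+C2)``
for membrane fluidity, the JC-1 aggregate/monomer ratio ``C1/C2`` for
mitochondrial potential, or any user formula.  Expressions support + - * /
^ (right-associative power), unary minus, parentheses and numeric
constants; nothing else is reachable, so evaluating untrusted config files
is safe.

Pixels whose expression evaluates to a non-finite value (division by zero,
0/0, overflow) or falls outside the configured valid range are *removed*:
set to NaN and counted, never silently zeroed.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional, Sequence, Union

import numpy as np

from .errors import ConfigError, ExpressionError, SpectromapError
from .model import BetaConfig, ImageStack

__all__ = [
    "parse_expression",
    "Evaluator",
    "BetaMap",
    "compute_beta_map",
    "beta_stats",
    "beta_histogram",
    "reconstruct_spectrum",
    "SpectrumProfile",
    "phasor_transform",
    "PhasorPoint",
    "ratio_beta",
]

_IDENTIFIERS = ("C1", "C2", "C3", "C4")


# ---------------------------------------------------------------------------
# expression grammar
#
#   expr   := term (('+' | '-') term)*
#   term   := factor (('*' | '/' | '×' | '÷') factor)*
#   factor := '-' factor | power
#   power  := atom ('^' factor)?          (right-associative)
#   atom   := NUMBER | IDENT | '(' expr ')'
# ---------------------------------------------------------------------------

_Node = Union[tuple, float, str]


class _Parser:
    def __init__(self, text: str):
        self.text = text
        self.pos = 0

    def _skip_ws(self) -> None:
        while self.pos < len(self.text) and self.text[self.pos].isspace():
            self.pos += 1

    def _peek(self) -> str:
        self._skip_ws()
        return self.text[self.pos] if self.pos < len(self.text) else ""

    def _fail(self, msg: str) -> None:
        raise ExpressionError(f"{msg} at position {self.pos}", position=self.pos)

    def parse(self) -> _Node:
        node = self.expr()
        self._skip_ws()
        if self.pos != len(self.text):
            self._fail(f"unexpected character {self.text[self.pos]!r}")
        return node

    def expr(self) -> _Node:
        node = self.term()
        while self._peek() in ("+", "-"):
            op = self.text[self.pos]
            self.pos += 1
            node = (op, node, self.term())
        return node

    def term(self) -> _Node:
        node = self.factor()
        while self._peek() in ("*", "/", "×", "÷"):
            op = self.text[self.pos]
            self.pos += 1
            node = ("*" if op in "*×" else "/", node, self.factor())
        return node

    def factor(self) -> _Node:
        if self._peek() == "-":
            self.pos += 1
            return ("neg", self.factor())
        return self.power()

    def power(self) -> _Node:
        base = self.atom()
        if self._peek() == "^":
            self.pos += 1
            return ("^", base, self.factor())  # right-associative
        return base

    def atom(self) -> _Node:
        ch = self._peek()
        if ch == "(":
            self.pos += 1
            node = self.expr()
            if self._peek() != ")":
                self._fail("expected ')'")
            self.pos += 1
            return node
        if ch.isdigit() or ch == ".":
            start = self.pos
            while self.pos < len(self.text) and (
                self.text[self.pos].isdigit() or self.text[self.pos] in ".eE"
                or (self.text[self.pos] in "+-" and self.text[self.pos - 1] in "eE")
            ):
                self.pos += 1
            try:
                return float(self.text[start : self.pos])
            except ValueError:
                self.pos = start
                self._fail(f"bad number {self.text[start:self.pos + 1]!r}")
        if ch.isalpha():
            start = self.pos
            while self.pos < len(self.text) and self.text[self.pos].isalnum():
                self.pos += 1
            name = self.text[start : self.pos]
            if name not in _IDENTIFIERS:
                self.pos = start
                self._fail(f"unknown identifier {name!r} (use C1..C4)")
            return name
        self._fail("expected number, identifier or '('")
        raise AssertionError  # unreachable


def _eval_node(node: _Node, env: dict[str, np.ndarray]) -> np.ndarray:
    if isinstance(node, float):
        return np.float64(node)
    if isinstance(node, str):
        return env[node]
    op = node[0]
    if op == "neg":
        return -_eval_node(node[1], env)
    a = _eval_node(node[1], env)
    b = _eval_node(node[2], env)
    with np.errstate(divide="ignore", invalid="ignore", over="ignore"):
        if op == "+":
            return a + b
        if op == "-":
            return a - b
        if op == "*":
            return a * b
        if op == "/":
            return np.divide(a, b)
        if op == "^":
            return np.power(a, b)
    raise AssertionError(f"unknown op {op!r}")


def _collect_idents(node: _Node, out: set[str]) -> None:
    if isinstance(node, str):
        out.add(node)
    elif isinstance(node, tuple):
        for child in node[1:]:
            _collect_idents(child, out)


@dataclass
class Evaluator:
    """A parsed beta expression; call with arrays bound to C1..C4."""

    expression: str
    _tree: _Node
    identifiers: frozenset[str]

    def __call__(self, **channels: np.ndarray) -> np.ndarray:
        missing = self.identifiers - set(channels)
        if missing:
            raise ConfigError(f"unbound identifiers: {sorted(missing)}")
        return _eval_node(self._tree, channels)


def parse_expression(expression: str) -> Evaluator:
    """Parse a beta formula into a safe evaluator.

    Raises :class:`ExpressionError` with the character position on syntax
    errors; identifiers other than C1..C4 are rejected.
    """
    tree = _Parser(expression).parse()
    idents: set[str] = set()
    _collect_idents(tree, idents)
    return Evaluator(expression=expression, _tree=tree, identifiers=frozenset(idents))


# ---------------------------------------------------------------------------
# beta maps
# ---------------------------------------------------------------------------


@dataclass
class BetaMap:
    """Pixel-wise beta image for one (t,z) slice and one target region.

    ``values`` is NaN outside the mask and at removed pixels;
    ``removed_count`` counts removed pixels *inside* the mask.
    """

    values: np.ndarray
    removed_count: int
    t: int = 0
    z: int = 0
    target: str = "membrane"


def compute_beta_map(
    stack: ImageStack,
    mask: np.ndarray,
    config: BetaConfig,
    t: int = 0,
    z: int = 0,
) -> BetaMap:
    """Evaluate the beta expression inside ``mask`` for slice (t, z).

    Only masked pixels are ever read; pixels yielding non-finite values or
    values outside ``config.valid_range`` are removed (NaN) and counted.
    """
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != stack.shape_yx:
        raise ConfigError(
            f"mask shape {mask.shape} != image shape {stack.shape_yx}"
        )
    evaluator = parse_expression(config.expression)
    unbound = evaluator.identifiers - set(config.channel_binding)
    if unbound:
        raise ConfigError(f"expression uses unbound identifiers {sorted(unbound)}")
    values = np.full(stack.shape_yx, np.nan, dtype=np.float64)
    if not mask.any():
        warnings.warn("compute_beta_map: empty mask", stacklevel=2)
        return BetaMap(values=values, removed_count=0, t=t, z=z, target=config.target)
    env = {}
    for ident in evaluator.identifiers:
        ch = config.channel_binding[ident]
        if not (0 <= ch < stack.n_channels):
            raise ConfigError(f"{ident} bound to channel {ch}, out of range")
        env[ident] = stack.plane(t, z, ch).astype(np.float64)[mask]
    result = np.asarray(evaluator(**env), dtype=np.float64)
    result = np.broadcast_to(result, (int(mask.sum()),)).copy()
    bad = ~np.isfinite(result)
    if config.valid_range is not None:
        lo, hi = config.valid_range
        with np.errstate(invalid="ignore"):
            bad |= (result < lo) | (result > hi)
    result[bad] = np.nan
    values[mask] = result
    return BetaMap(
        values=values, removed_count=int(bad.sum()), t=t, z=z, target=config.target
    )


def beta_stats(beta_map: BetaMap) -> dict:
    """Median, standard deviation and count over valid (non-NaN) pixels."""
    valid = beta_map.values[np.isfinite(beta_map.values)]
    if valid.size == 0:
        raise SpectromapError("beta_stats: no valid pixels")
    return {
        "median": float(np.median(valid)),
        "std": float(np.std(valid)),
        "count": int(valid.size),
    }


def beta_histogram(
    beta_map: BetaMap, bins: int = 64, range: Optional[tuple[float, float]] = None
) -> tuple[np.ndarray, np.ndarray]:
    """Histogram of valid beta values; counts sum to the valid-pixel count."""
    if bins < 1:
        raise ConfigError("bins must be >= 1")
    valid = beta_map.values[np.isfinite(beta_map.values)]
    if valid.size == 0:
        raise SpectromapError("beta_histogram: no valid pixels")
    if range is None:
        range = (float(valid.min()), float(valid.max()) + 1e-12)
    counts, edges = np.histogram(valid, bins=bins, range=range)
    return counts, edges


# ---------------------------------------------------------------------------
# spectrum and phasor
# ---------------------------------------------------------------------------


@dataclass
class SpectrumProfile:
    """Per-channel mean intensity over a mask (the reconstructed spectrum)."""

    intensities: np.ndarray
    channel_centers_nm: Optional[tuple[float, ...]]
    pixel_count: int


def reconstruct_spectrum(
    stack: ImageStack, mask: np.ndarray, t: int = 0, z: int = 0
) -> SpectrumProfile:
    """Mean intensity per channel over the masked pixels of slice (t, z)."""
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise SpectromapError("reconstruct_spectrum: empty mask")
    planes = stack.slice_channels(t, z).astype(np.float64)
    means = planes[:, mask].mean(axis=1)
    return SpectrumProfile(
        intensities=means,
        channel_centers_nm=stack.channel_centers_nm,
        pixel_count=int(mask.sum()),
    )


@dataclass
class PhasorPoint:
    """First-harmonic (by default) spectral phasor coordinates."""

    G: float
    S: float
    harmonic: int = 1


def phasor_transform(
    spectrum: Union[SpectrumProfile, Sequence[float], np.ndarray], n: int = 1
) -> PhasorPoint:
    """Spectral phasor of a non-negative spectrum over N channels.

    G = sum_k I_k cos(2 pi n k / N) / sum_k I_k and likewise with sine for
    S.  Any non-negative spectrum maps inside the unit circle; a
    zero-total spectrum yields a NaN point (to be excluded from plots).
    """
    if isinstance(spectrum, SpectrumProfile):
        intensities = np.asarray(spectrum.intensities, dtype=np.float64)
    else:
        intensities = np.asarray(spectrum, dtype=np.float64)
    total = intensities.sum()
    if total <= 0:
        return PhasorPoint(G=float("nan"), S=float("nan"), harmonic=n)
    k = np.arange(intensities.size)
    ang = 2.0 * np.pi * n * k / intensities.size
    return PhasorPoint(
        G=float((intensities * np.cos(ang)).sum() / total),
        S=float((intensities * np.sin(ang)).sum() / total),
        harmonic=n,
    )


def ratio_beta(
    stack: ImageStack,
    mask: np.ndarray,
    red_channel: int,
    green_channel: int,
    t: int = 0,
    z: int = 0,
) -> BetaMap:
    """Preset intensity-ratio beta ``I_red / I_green`` on an organelle mask.

    This is the JC-1 mitochondrial-potential readout: aggregates (red) over
    monomers (green); zero-denominator pixels are removed.
    """
    config = BetaConfig(
        expression="C1/C2",
        channel_binding={"C1": red_channel, "C2": green_channel},
        target="cytosol",
    )
    return compute_beta_map(stack, mask, config, t=t, z=z)
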