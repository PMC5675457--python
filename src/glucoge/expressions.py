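"""Predictor expressions: the phenotype language of the glucose grammar.

A predictor combines four blocks — lagged-glucose terms, lagged-Ra terms,
lagged-IOB terms, and an optional circadian sinusoid — joined by arithmetic
operators:

    pred(n) = (G(n) op1 Ra(n) op2 IOB(n)) op3 Circadian(n)

Each block is a sum of terms ``preop(X[n - lag] / alpha) op delta`` where the
lag is in 5-min CGM samples, ``alpha`` and ``delta`` are grammar constants in
[0, 99.9], and ``preop`` is a chain of unary operators. The value is the
forecast of CGM glucose one prediction horizon (24 samples = 120 min) past
sample ``n``.

All arithmetic is protected so any expression the grammar can produce
evaluates to a finite number on finite inputs: division by zero yields 1,
``log`` and ``sqrt`` act on magnitudes with ``log(0) = 0``, ``pow`` squares
with clipping, ``exp`` has a clipped argument, and every intermediate is
clipped to ``±1e10`` with NaN mapped to 0.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .signals import UniformSignal, AlignmentError

__all__ = [
    "ExpressionTerm",
    "CircadianTerm",
    "PredictorExpression",
    "PhenotypeError",
    "parse_phenotype",
    "evaluate",
    "evaluate_series",
    "PREDICTION_HORIZON_SAMPLES",
    "MAX_LAG_SAMPLES",
    "SAMPLES_PER_DAY",
    "CIRCADIAN_MAX_AMPLITUDE",
]

#: Forecast lead time in 5-min CGM samples (120 min).
PREDICTION_HORIZON_SAMPLES = 24
#: History needed before the first prediction can be made, in samples.
MAX_LAG_SAMPLES = 24
#: Five-minute samples per day; the circadian frequency unit is cycles/day.
SAMPLES_PER_DAY = 288
#: Amplitude cap for the circadian block, mg/dl: 20% of a 140 mg/dl
#: representative mean glucose, the grammar's stated day-to-day bound.
CIRCADIAN_MAX_AMPLITUDE = 28.0

_PREVINI_GRID = frozenset({0, 1, 2} | set(range(4, 24, 2)))
_PREVFIN_GRID = frozenset({1, 2} | set(range(4, 26, 2)))
_PREOPS = ("sqrt", "sin", "log", "pow", "exp", "cos")
_CLIP = 1e10


class PhenotypeError(ValueError):
    """Phenotype text that is not a well-formed predictor expression."""


# ---------------------------------------------------------------- protection

def _guard(v):
    v = np.where(np.isnan(v), 0.0, v)
    return np.clip(v, -_CLIP, _CLIP)


def _pdiv(a, b):
    b = np.asarray(b, dtype=float)
    safe = np.where(np.abs(b) < 1e-12, 1.0, b)
    return _guard(np.where(np.abs(b) < 1e-12, 1.0, np.asarray(a, dtype=float) / safe))


_PREOP_FUNCS = {
    "sqrt": lambda x: np.sqrt(np.abs(x)),
    "sin": np.sin,
    "cos": np.cos,
    "log": lambda x: np.where(np.abs(x) < 1e-300, 0.0,
                              np.log(np.maximum(np.abs(x), 1e-300))),
    "pow": lambda x: np.clip(np.asarray(x, dtype=float) ** 2, -_CLIP, _CLIP),
    "exp": lambda x: np.exp(np.clip(x, -50.0, 50.0)),
}


def _apply_op(a, op: str, b):
    if op == "+":
        return _guard(np.asarray(a, dtype=float) + b)
    if op == "-":
        return _guard(np.asarray(a, dtype=float) - b)
    if op == "*":
        return _guard(np.asarray(a, dtype=float) * b)
    if op == "/":
        return _pdiv(a, b)
    raise PhenotypeError(f"unknown operator {op!r}")


def _neutral(op: str) -> float:
    return 0.0 if op in "+-" else 1.0


# ------------------------------------------------------------------- terms

@dataclass(frozen=True)
class ExpressionTerm:
    """One term ``preop(source[n - lag] / scale) offset_op offset``."""

    source: str              # 'G', 'Ra' or 'IOB'
    lag: int                 # 5-min samples; PrevIni grid value
    scale: float             # alpha, divisor constant
    offset_op: str           # op joining the scaled value and the offset
    offset: float            # delta
    preops: tuple[str, ...] = ()
    lag_end: int = 24        # PrevFin; must exceed lag

    def __post_init__(self) -> None:
        if self.source not in ("G", "Ra", "IOB"):
            raise PhenotypeError(f"unknown signal source {self.source!r}")
        if self.lag not in _PREVINI_GRID:
            raise PhenotypeError(f"lag {self.lag} not on the PrevIni grid")
        if self.lag_end not in _PREVFIN_GRID:
            raise PhenotypeError(f"lag_end {self.lag_end} not on the PrevFin grid")
        if self.lag >= self.lag_end:
            # The window constraint PrevIni < PrevFin is enforced by
            # normalization: the pair is reordered (and widened by one grid
            # step when equal) rather than invalidating the phenotype.
            new_lag = self.lag_end if self.lag_end in _PREVINI_GRID else self.lag
            new_end = self.lag if self.lag in _PREVFIN_GRID else self.lag_end
            if new_lag >= new_end:
                new_end = min(x for x in _PREVFIN_GRID if x > new_lag)
            object.__setattr__(self, "lag", new_lag)
            object.__setattr__(self, "lag_end", new_end)
        for p in self.preops:
            if p not in _PREOPS:
                raise PhenotypeError(f"unknown pre-operator {p!r}")
        for c in (self.scale, self.offset):
            if not (0.0 <= c <= 99.9):
                raise PhenotypeError(f"constant {c} outside the grammar range [0, 99.9]")

    def _eval(self, x):
        v = _pdiv(x, self.scale)
        for p in reversed(self.preops):  # textual chain f g x reads f(g(x))
            v = _guard(_PREOP_FUNCS[p](v))
        return _apply_op(v, self.offset_op, self.offset)

    def to_text(self) -> str:
        return (f"Get{self.source}({self.lag},{self.lag_end},{self.offset_op},"
                f"{''.join(self.preops)},({self.scale:04.1f}),({self.offset:04.1f}))")


@dataclass(frozen=True)
class CircadianTerm:
    """``amplitude combine_op cos(omega * n + phase)`` with n in samples.

    ``freq_cte`` is the grammar constant read as cycles/day, so the angular
    frequency is ``freq_cte * 2*pi / 288`` rad/sample. The amplitude is
    clipped to :data:`CIRCADIAN_MAX_AMPLITUDE` at evaluation time.
    """

    amplitude: float
    freq_cte: float
    phase: float
    combine_op: str = "*"

    def __post_init__(self) -> None:
        if self.combine_op not in ("*", "/"):
            raise PhenotypeError("circadian combine operator must be * or /")
        for c in (self.amplitude, self.freq_cte, self.phase):
            if not (0.0 <= c <= 99.9):
                raise PhenotypeError(f"constant {c} outside the grammar range [0, 99.9]")

    @property
    def angular_freq(self) -> float:
        return self.freq_cte * 2.0 * np.pi / SAMPLES_PER_DAY

    def _eval(self, n):
        amp = min(self.amplitude, CIRCADIAN_MAX_AMPLITUDE)
        wave = np.cos(self.angular_freq * np.asarray(n, dtype=float) + self.phase)
        return _apply_op(amp, self.combine_op, wave)

    def to_text(self) -> str:
        return (f"GetCircadian({self.combine_op},({self.amplitude:04.1f}),"
                f"({self.freq_cte:04.1f}),({self.phase:04.1f}))")


@dataclass(frozen=True)
class PredictorExpression:
    """The full predictor: three term blocks, optional circadian, three joins.

    ``ops`` holds (op joining G and Ra, op joining with IOB, op joining with
    the circadian block). An empty block stands for the neutral element of
    the operator that joins it (0 for +/-, 1 for * and /).
    """

    g_terms: tuple[ExpressionTerm, ...] = ()
    ra_terms: tuple[ExpressionTerm, ...] = ()
    iob_terms: tuple[ExpressionTerm, ...] = ()
    circadian: CircadianTerm | None = None
    ops: tuple[str, str, str] = ("+", "+", "+")

    def __post_init__(self) -> None:
        for op in self.ops:
            if op not in "+-*/":
                raise PhenotypeError(f"unknown operator {op!r}")
        for t in self.g_terms:
            if t.source != "G":
                raise PhenotypeError("G block holds a non-G term")
        for t in self.ra_terms:
            if t.source != "Ra":
                raise PhenotypeError("Ra block holds a non-Ra term")
        for t in self.iob_terms:
            if t.source != "IOB":
                raise PhenotypeError("IOB block holds a non-IOB term")

    @property
    def max_lag(self) -> int:
        lags = [t.lag for t in self.g_terms + self.ra_terms + self.iob_terms]
        return max(lags, default=0)

    def to_text(self) -> str:
        """Canonical phenotype text; round-trips through :func:`parse_phenotype`."""
        g = "".join(t.to_text() for t in self.g_terms)
        ra = "".join(t.to_text() for t in self.ra_terms)
        iob = "".join(t.to_text() for t in self.iob_terms)
        circ = self.circadian.to_text() if self.circadian else ""
        o1, o2, o3 = self.ops
        return f"ExprG^=({g}{o1}{ra}{o2}{iob}){o3}{circ}"

    @classmethod
    def persistence(cls) -> "PredictorExpression":
        """The naive forecaster pred(n) = G[n]: current glucose carried forward."""
        term = ExpressionTerm("G", 0, 1.0, "+", 0.0)
        return cls(g_terms=(term,), ops=("+", "+", "+"))


def _block_value(terms, values: np.ndarray, n: np.ndarray, join_op: str):
    if not terms:
        return np.full(n.shape, _neutral(join_op))
    acc = np.zeros(n.shape)
    for t in terms:
        acc = _guard(acc + t._eval(values[n - t.lag]))
    return acc


def evaluate_series(expr: PredictorExpression, g: np.ndarray, ra: np.ndarray,
                    iob: np.ndarray, n: np.ndarray) -> np.ndarray:
    """Evaluate ``expr`` at every sample index in ``n`` (vectorized).

    ``g``, ``ra`` and ``iob`` are aligned arrays on the 5-min CGM grid; each
    returned value is the 120-min-ahead forecast made at the corresponding
    index. Indices must leave :data:`MAX_LAG_SAMPLES` of history.
    """
    n = np.asarray(n, dtype=int)
    if n.size and n.min() < MAX_LAG_SAMPLES:
        raise ValueError(f"prediction indices need {MAX_LAG_SAMPLES} samples of history")
    if not (len(g) == len(ra) == len(iob)):
        raise AlignmentError("G, Ra and IOB arrays must have equal length")
    op1, op2, op3 = expr.ops
    core = _apply_op(_block_value(expr.g_terms, g, n, op1), op1,
                     _block_value(expr.ra_terms, ra, n, op1))
    core = _apply_op(core, op2, _block_value(expr.iob_terms, iob, n, op2))
    if expr.circadian is None:
        circ = np.full(n.shape, _neutral(op3))
    else:
        circ = expr.circadian._eval(n)
    return _apply_op(core, op3, circ)


def evaluate(expr: PredictorExpression, g: UniformSignal, ra: UniformSignal,
             iob: UniformSignal, n: int) -> float:
    """Scalar evaluation at sample index ``n`` of three aligned signals."""
    if not (g.same_grid(ra) and g.same_grid(iob)):
        raise AlignmentError("G, Ra and IOB signals must share the sampling grid")
    return float(evaluate_series(expr, g.values, ra.values, iob.values,
                                 np.array([n]))[0])


# ------------------------------------------------------------------ parsing

class _Scanner:
    def __init__(self, text: str):
        self.text = text
        self.pos = 0

    def expect(self, lit: str) -> None:
        if not self.text.startswith(lit, self.pos):
            raise PhenotypeError(
                f"expected {lit!r} at position {self.pos} in {self.text[:80]!r}...")
        self.pos += len(lit)

    def peek(self, lit: str) -> bool:
        return self.text.startswith(lit, self.pos)

    def read_op(self) -> str:
        if self.pos >= len(self.text) or self.text[self.pos] not in "+-*/":
            raise PhenotypeError(f"expected an operator at position {self.pos}")
        op = self.text[self.pos]
        self.pos += 1
        return op

    def read_call_args(self) -> list[str]:
        """Read a balanced ``(...)`` and split it on top-level commas."""
        self.expect("(")
        depth = 1
        start = self.pos
        args, buf = [], []
        while depth > 0:
            if self.pos >= len(self.text):
                raise PhenotypeError("unterminated call")
            ch = self.text[self.pos]
            if ch == "(":
                depth += 1
            elif ch == ")":
                depth -= 1
                if depth == 0:
                    self.pos += 1
                    break
            if ch == "," and depth == 1:
                args.append("".join(buf))
                buf = []
            else:
                buf.append(ch)
            self.pos += 1
        args.append("".join(buf))
        return args


def _parse_cte(text: str) -> float:
    text = text.strip()
    if not (text.startswith("(") and text.endswith(")")):
        raise PhenotypeError(f"malformed constant {text!r}")
    try:
        return float(text[1:-1])
    except ValueError:
        raise PhenotypeError(f"malformed constant {text!r}") from None


def _parse_preops(text: str) -> tuple[str, ...]:
    out: list[str] = []
    pos = 0
    while pos < len(text):
        for name in _PREOPS:
            if text.startswith(name, pos):
                out.append(name)
                pos += len(name)
                break
        else:
            raise PhenotypeError(f"unknown pre-operator chain {text!r}")
    return tuple(out)


def _parse_terms(sc: _Scanner, source: str) -> tuple[ExpressionTerm, ...]:
    terms = []
    head = f"Get{source}"
    while sc.peek(head + "("):
        sc.pos += len(head)
        args = sc.read_call_args()
        if len(args) != 6:
            raise PhenotypeError(f"{head} expects 6 arguments, got {len(args)}")
        terms.append(ExpressionTerm(
            source=source,
            lag=int(args[0]),
            lag_end=int(args[1]),
            offset_op=args[2],
            preops=_parse_preops(args[3]),
            scale=_parse_cte(args[4]),
            offset=_parse_cte(args[5]),
        ))
    return tuple(terms)


def parse_phenotype(text: str) -> PredictorExpression:
    """Parse a derived phenotype string into a :class:`PredictorExpression`.

    Raises :class:`PhenotypeError` for text outside the phenotype language,
    including terms whose lag window violates PrevIni < PrevFin.
    """
    sc = _Scanner(text.strip())
    sc.expect("ExprG^=(")
    g_terms = _parse_terms(sc, "G")
    op1 = sc.read_op()
    ra_terms = _parse_terms(sc, "Ra")
    op2 = sc.read_op()
    iob_terms = _parse_terms(sc, "IOB")
    sc.expect(")")
    op3 = sc.read_op()
    circ = None
    if sc.peek("GetCircadian("):
        sc.pos += len("GetCircadian")
        args = sc.read_call_args()
        if len(args) != 4:
            raise PhenotypeError("GetCircadian expects 4 arguments")
        circ = CircadianTerm(
            combine_op=args[0],
            amplitude=_parse_cte(args[1]),
            freq_cte=_parse_cte(args[2]),
            phase=_parse_cte(args[3]),
        )
    if sc.pos != len(sc.text):
        raise PhenotypeError(f"trailing text {sc.text[sc.pos:]!r}")
    return PredictorExpression(g_terms=g_terms, ra_terms=ra_terms,
                               iob_terms=iob_terms, circadian=circ,
                               ops=(op1, op2, op3))
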