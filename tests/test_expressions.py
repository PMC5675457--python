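"""Phenotype parsing, protected evaluation, and the worked-example fixture."""

import math

import numpy as np
import pytest

from glucoge import (CircadianTerm, ExpressionTerm, Genotype,
                     PredictorExpression, PhenotypeError, UniformSignal,
                     evaluate, evaluate_series, map_genotype, parse_phenotype)

# ----------------------------------------------------------- choice encoder
# Builds a codon string for the shipped grammar by listing the production
# choice taken at every choice point of the leftmost derivation. Codon value
# = choice index (index < production count, so the mod is the identity).

_PREVINI = [0, 1, 2, 4, 6, 8, 10, 12, 14, 16, 18, 20, 22]
_PREVFIN = [1, 2, 4, 6, 8, 10, 12, 14, 16, 18, 20, 22, 24]
_PREOP_IDX = {"sqrt": 0, "sin": 1, "log": 2, "pow": 3, "exp": 4, "cos": 5}
_OPS = {"+": [0, 0], "-": [0, 1], "/": [1, 0], "*": [1, 1]}


def _enc_cte(text: str) -> list[int]:
    d1, d2, _, d3 = text
    return [int(d1), int(d2), int(d3)]


def _enc_preop(chain: tuple[str, ...]) -> list[int]:
    if not chain:
        return [7]  # λ
    if len(chain) == 1:
        return [_PREOP_IDX[chain[0]]]
    # recursive production, then the head and the rest of the chain
    return [6] + _enc_preop(chain[:1]) + _enc_preop(chain[1:])


def _enc_term(term: ExpressionTerm) -> list[int]:
    return ([0]  # pick the Get* production over λ
            + [_PREVINI.index(term.lag)]
            + [_PREVFIN.index(term.lag_end)]
            + _OPS[term.offset_op]
            + _enc_preop(term.preops)
            + _enc_cte(f"{term.scale:04.1f}")
            + _enc_cte(f"{term.offset:04.1f}"))


def encode_expression(expr: PredictorExpression) -> Genotype:
    codons: list[int] = []
    for block in (expr.g_terms, expr.ra_terms, expr.iob_terms):
        for t in block:
            codons += _enc_term(t)
        codons.append(1)  # λ closes the block
    o1, o2, o3 = expr.ops
    # leftmost order: G-block, op1, Ra-block, op2, IOB-block, op3, Circadian
    g_len = sum(len(_enc_term(t)) for t in expr.g_terms) + 1
    ra_len = sum(len(_enc_term(t)) for t in expr.ra_terms) + 1
    iob_len = sum(len(_enc_term(t)) for t in expr.iob_terms) + 1
    codons = (codons[:g_len] + _OPS[o1] + codons[g_len:g_len + ra_len] + _OPS[o2]
              + codons[g_len + ra_len:g_len + ra_len + iob_len] + _OPS[o3])
    if expr.circadian is None:
        codons.append(1)
    else:
        c = expr.circadian
        codons += ([0] + [{"/": 0, "*": 1}[c.combine_op]]
                   + _enc_cte(f"{c.amplitude:04.1f}")
                   + _enc_cte(f"{c.freq_cte:04.1f}")
                   + _enc_cte(f"{c.phase:04.1f}"))
    return Genotype(tuple(codons))


def _signals(g=100.0, ra=0.5, iob=2.0, n=120):
    mk = lambda v: UniformSignal(np.full(n, v), t0=0.0, dt=5.0)
    return mk(g), mk(ra), mk(iob)


class TestEvaluation:
    def test_persistence_returns_current_cgm(self):
        g, ra, iob = _signals(g=137.0)
        val = evaluate(PredictorExpression.persistence(), g, ra, iob, n=30)
        assert val == pytest.approx(137.0)

    def test_protected_log_of_zero_is_finite(self):
        term = ExpressionTerm("G", 0, 1.0, "+", 0.0, preops=("log",))
        expr = PredictorExpression(g_terms=(term,))
        vals = evaluate_series(expr, np.zeros(60) + 1e-320, np.ones(60),
                               np.ones(60), np.array([30]))
        assert np.isfinite(vals[0])

    def test_protected_division_by_zero(self):
        term = ExpressionTerm("G", 0, 0.0, "+", 5.0)  # divisor constant 0
        expr = PredictorExpression(g_terms=(term,))
        g, ra, iob = _signals()
        assert evaluate(expr, g, ra, iob, 30) == pytest.approx(1.0 + 5.0)

    def test_misaligned_signals_raise(self):
        from glucoge import AlignmentError

        g, ra, iob = _signals()
        bad = UniformSignal(np.full(len(g), 0.5), t0=0.0, dt=1.0)
        with pytest.raises(AlignmentError):
            evaluate(PredictorExpression.persistence(), g, bad, iob, 30)

    def test_insufficient_history_raises(self):
        g, ra, iob = _signals()
        with pytest.raises(ValueError):
            evaluate(PredictorExpression.persistence(), g, ra, iob, 10)

    def test_lag_window_normalized_not_rejected(self):
        # PrevIni >= PrevFin is repaired by reordering, keeping the phenotype
        # valid; equal values widen the window by one grid step.
        t = ExpressionTerm("G", 20, 1.0, "+", 0.0, lag_end=4)
        assert (t.lag, t.lag_end) == (4, 20)
        t2 = ExpressionTerm("G", 22, 1.0, "+", 0.0, lag_end=22)
        assert (t2.lag, t2.lag_end) == (22, 24)


class TestSerialization:
    def test_text_round_trip(self):
        expr = PredictorExpression(
            g_terms=(ExpressionTerm("G", 2, 12.5, "*", 3.0, preops=("log", "sin")),),
            ra_terms=(ExpressionTerm("Ra", 0, 1.0, "-", 90.0, preops=("sin",)),),
            iob_terms=(),
            circadian=CircadianTerm(19.9, 5.5, 0.0, "*"),
            ops=("*", "-", "-"),
        )
        assert parse_phenotype(expr.to_text()) == expr

    def test_malformed_text_raises(self):
        with pytest.raises(PhenotypeError):
            parse_phenotype("ExprG^=(GetG(0,1)+)+")
        with pytest.raises(PhenotypeError):
            parse_phenotype("nonsense")


class TestWorkedExample:
    """The published worked phenotype, as a grammar-derivability fixture.

    The fixture mirrors the printed breakfast model's structure —
    (G * Ra - IOB) - Circadian with a three-term glucose block, a sine Ra
    term, a two-term IOB block and a sinusoidal circadian block — with lags
    and constants moved onto the grammar's grids where the printed values
    fall outside them (lag 24 -> 22; 909.1 -> 90.9).
    """

    @staticmethod
    def fixture_expression() -> PredictorExpression:
        return PredictorExpression(
            g_terms=(
                ExpressionTerm("G", 22, 57.9, "*", 3.7, preops=("log",), lag_end=24),
                ExpressionTerm("G", 22, 2.0, "*", 57.7, lag_end=24),
                ExpressionTerm("G", 22, 2.7, "*", 90.9, lag_end=24),
            ),
            ra_terms=(
                ExpressionTerm("Ra", 22, 2.7, "-", 90.0, preops=("sin",), lag_end=24),
            ),
            iob_terms=(
                ExpressionTerm("IOB", 0, 4.1, "*", 2.0, preops=("sin",), lag_end=1),
                ExpressionTerm("IOB", 6, 4.9, "*", 0.2, preops=("log",), lag_end=8),
            ),
            circadian=CircadianTerm(19.9, 5.5, 0.0, "*"),
            ops=("*", "-", "-"),
        )

    def test_derivable_from_shipped_grammar(self, grammar):
        expr = self.fixture_expression()
        genotype = encode_expression(expr)
        result = map_genotype(genotype, grammar, max_wraps=0)
        assert result.valid
        assert result.phenotype == expr.to_text()
        assert parse_phenotype(result.phenotype) == expr

    def test_value_matches_manual_arithmetic(self):
        # Hand evaluation on constant inputs, written out independently.
        expr = self.fixture_expression()
        g0, ra0, iob0, n = 100.0, 0.5, 2.0, 50
        g_block = (math.log(g0 / 57.9) * 3.7
                   + (g0 / 2.0) * 57.7
                   + (g0 / 2.7) * 90.9)
        ra_block = math.sin(ra0 / 2.7) - 90.0
        iob_block = (math.sin(iob0 / 4.1) * 2.0
                     + math.log(iob0 / 4.9) * 0.2)
        circ = 19.9 * math.cos(5.5 * 2.0 * math.pi / 288.0 * n)
        expected = (g_block * ra_block - iob_block) - circ
        g, ra, iob = _signals(g0, ra0, iob0)
        assert evaluate(expr, g, ra, iob, n) == pytest.approx(expected, rel=1e-12)
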