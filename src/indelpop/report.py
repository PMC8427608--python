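"""Publication-style table rendering for locus summaries and association scans.

Rounding follows the conventions of the field's genetic-parameter tables:
genotype frequencies, Ho and He to 2 decimals; allele frequencies, Ne, PIC
and HWE p-values to 3 decimals; association cells as "mean ± sem" with
superscript-style letter groups and the overall P at 3 decimals.  Half-up
rounding is used throughout (so 0.0305 renders as 0.031), applied only at
render time — all upstream values stay at full precision.
"""

from __future__ import annotations

from decimal import ROUND_HALF_UP, Decimal

from .association import AssocResult
from .datamodel import ValidationError
from .popgen import LocusSummary

__all__ = ["round_half_up", "render_locus_summary_table", "render_assoc_table"]


def round_half_up(x: float, digits: int) -> float:
    """Decimal round-half-up (unlike banker's rounding of built-in round)."""
    q = Decimal(10) ** -digits
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


def _fmt(x: float, digits: int) -> str:
    return f"{round_half_up(x, digits):.{digits}f}"


_SUMMARY_HEADER = ["population", "n", "freq_DD", "freq_ID", "freq_II",
                   "p_D", "p_I", "Ho", "He", "Ne", "PIC", "P_HWE"]


def render_locus_summary_table(summaries: list[LocusSummary],
                               sep: str = "\t") -> str:
    """Render locus summaries, one population per row."""
    if not summaries:
        raise ValidationError("no locus summaries to render")
    lines = [sep.join(_SUMMARY_HEADER)]
    for s in summaries:
        lines.append(sep.join([
            s.population, str(s.n),
            _fmt(s.freq_DD, 2), _fmt(s.freq_ID, 2), _fmt(s.freq_II, 2),
            _fmt(s.p_D, 3), _fmt(s.p_I, 3),
            _fmt(s.Ho, 2), _fmt(s.He, 2),
            _fmt(s.Ne, 3), _fmt(s.PIC, 3),
            _fmt(s.hwe_p_exact, 3),
        ]))
    return "\n".join(lines)


def format_cell(mean: float, sem: float, letters: str,
                mean_digits: int = 3, sem_digits: int = 2) -> str:
    """One association-table cell: ``mean ± sem^letters``."""
    cell = f"{_fmt(mean, mean_digits)} ± {_fmt(sem, sem_digits)}"
    if letters:
        cell += f"^{letters}^"
    return cell


def render_assoc_table(results: list[AssocResult], sep: str = "\t",
                       genotype_order: tuple[str, ...] = ("DD", "ID", "II")
                       ) -> str:
    """Render an association scan: one trait per row, one cell per genotype."""
    if not results:
        raise ValidationError("no association results to render")
    header = ["trait", "model"]
    header += [f"{g} (mean ± sem)" for g in genotype_order]
    header += ["P", "a", "d"]
    lines = [sep.join(header)]
    for r in results:
        cells = []
        for g in genotype_order:
            if g in r.cells:
                c = r.cells[g]
                cells.append(format_cell(c.ls_mean, c.sem, c.letters))
            else:
                cells.append("—")
        a = _fmt(r.additive_a, 3) if r.additive_a is not None else "—"
        d = _fmt(r.dominance_d, 3) if r.dominance_d is not None else "—"
        lines.append(sep.join([r.trait_code, r.model] + cells
                              + [_fmt(r.p_overall, 3), a, d]))
    return "\n".join(lines)
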