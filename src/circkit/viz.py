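"""Deterministic SVG rendering of circRNA isoform and protein-domain views.

Two plots are produced:

* a transcript plot — one red row per representative transcript (exon
  boxes joined by intron lines, genomic x-axis) with, below it, one row
  per circRNA spanning its backsplice exon pair, green when an ORF was
  predicted and blue when not;
* a protein plot — the full-length parental protein with its annotated
  domains on top and each circRNA-derived ORF aligned underneath at its
  parental residue interval, novel overhangs drawn as hatched extensions.

Rendering is a pure function of its input: no timestamps, no random ids,
fixed decimal formatting — identical inputs yield byte-identical SVG.
Every drawn entity carries a ``class`` attribute naming its color class,
so tests can verify structure by parsing the XML rather than comparing
pixels.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from xml.sax.saxutils import escape

#: Default color per class; the figure legend colors are configurable.
COLORS = {
    "reference": "#CC0000",
    "orf_positive": "#2E8B57",
    "orf_negative": "#1F6FB2",
    "domain": "#D4A017",
    "orf_segment": "#555555",
}

#: Palette cycled over source transcripts in the protein plot, assigned in
#: order of first appearance.
TRANSCRIPT_PALETTE = [
    "#4C72B0", "#DD8452", "#55A868", "#C44E52", "#8172B3", "#937860",
]

_W = 1000.0  # drawing width, px
_MARGIN = 60.0
_ROW_H = 14.0
_ROW_GAP = 8.0


def _fmt(x: float) -> str:
    return f"{x:.2f}"


@dataclass
class TrackLayout:
    """Resolved plot rows: (label, intervals in plot x-coords, color class)."""

    rows: list[tuple[str, list[tuple[float, float]], str]] = field(
        default_factory=list
    )


def _scale(lo: int, hi: int):
    span = max(hi - lo, 1)

    def to_x(v: float) -> float:
        return _MARGIN + (v - lo) / span * (_W - 2 * _MARGIN)

    return to_x


def _svg_header(height: float) -> str:
    return (
        '<?xml version="1.0" encoding="UTF-8"?>\n'
        f'<svg xmlns="http://www.w3.org/2000/svg" version="1.1" '
        f'width="{_fmt(_W)}" height="{_fmt(height)}" '
        f'viewBox="0 0 {_fmt(_W)} {_fmt(height)}">\n'
        "<defs>\n"
        '<pattern id="hatch" width="6" height="6" '
        'patternUnits="userSpaceOnUse" patternTransform="rotate(45)">'
        '<line x1="0" y1="0" x2="0" y2="6" stroke="#888888" '
        'stroke-width="2"/></pattern>\n'
        "</defs>\n"
    )


def _rect(x, y, w, h, fill, cls, extra: str = "") -> str:
    return (
        f'<rect class="{cls}" x="{_fmt(x)}" y="{_fmt(y)}" '
        f'width="{_fmt(w)}" height="{_fmt(h)}" fill="{fill}"{extra}/>\n'
    )


def _line(x1, y1, x2, y2, stroke) -> str:
    return (
        f'<line x1="{_fmt(x1)}" y1="{_fmt(y1)}" x2="{_fmt(x2)}" '
        f'y2="{_fmt(y2)}" stroke="{stroke}" stroke-width="1.5"/>\n'
    )


def _text(x, y, s, size=10) -> str:
    return (
        f'<text x="{_fmt(x)}" y="{_fmt(y)}" font-family="monospace" '
        f'font-size="{size}">{escape(str(s))}</text>\n'
    )


def transcript_plot(
    assignments,
    models,
    orf_flags: dict,
    out_path,
    colors: dict | None = None,
) -> TrackLayout:
    """Render the circRNA isoform view for one gene to SVG.

    ``assignments`` are the gene's representative assignments;
    ``orf_flags`` maps junction key -> whether any ORF was predicted.
    Rows are ordered by transcript_id, then by junction key, so the output
    is deterministic.  Returns the resolved :class:`TrackLayout`.
    """
    assignments = [a for a in assignments if a.assigned]
    if not assignments:
        raise ValueError("no assigned circRNAs to plot")
    genes = {a.gene_id for a in assignments}
    if len(genes) > 1:
        raise ValueError(f"assignments span multiple genes: {sorted(genes)}")
    palette = dict(COLORS)
    if colors:
        palette.update(colors)

    models_by_id = (
        models if isinstance(models, dict)
        else {t.transcript_id: t for t in models}
    )
    by_tx: dict[str, list] = {}
    for a in sorted(assignments, key=lambda a: (a.transcript_id, a.junction.key)):
        by_tx.setdefault(a.transcript_id, []).append(a)

    lo = min(models_by_id[tid].span[0] for tid in by_tx)
    hi = max(models_by_id[tid].span[1] for tid in by_tx)
    to_x = _scale(lo, hi)

    layout = TrackLayout()
    body = []
    y = 30.0
    for tid in sorted(by_tx):
        t = models_by_id[tid]
        exon_iv = [(to_x(e.start), to_x(e.end)) for e in t.exons]
        layout.rows.append((tid, exon_iv, "reference"))
        body.append(_text(_MARGIN, y - 3, tid))
        mid = y + _ROW_H / 2
        span_lo, span_hi = t.span
        body.append(_line(to_x(span_lo), mid, to_x(span_hi), mid,
                          palette["reference"]))
        for x0, x1 in exon_iv:
            body.append(
                _rect(x0, y, max(x1 - x0, 1.0), _ROW_H,
                      palette["reference"], "reference")
            )
        y += _ROW_H + _ROW_GAP
        for a in by_tx[tid]:
            j = a.junction
            cls = "orf_positive" if orf_flags.get(j.key, False) else "orf_negative"
            x0, x1 = to_x(j.start), to_x(j.end)
            layout.rows.append((a.name, [(x0, x1)], cls))
            body.append(
                _rect(x0, y + 2, max(x1 - x0, 1.0), _ROW_H - 4,
                      palette[cls], cls)
            )
            body.append(_text(x1 + 4, y + _ROW_H - 4, a.name, size=8))
            y += _ROW_H + 2
        y += _ROW_GAP

    height = y + 20
    svg = _svg_header(height) + "".join(body) + "</svg>\n"
    with open(out_path, "w") as fh:
        fh.write(svg)
    return layout


@dataclass(frozen=True)
class DomainFeature:
    """A protein feature (UniProt-style) in 1-based inclusive residues."""

    protein_id: str
    feature_type: str
    description: str
    begin: int
    end: int

    def __post_init__(self):
        if not 1 <= self.begin <= self.end:
            raise ValueError(
                f"invalid domain interval [{self.begin}, {self.end}]"
            )


def read_domains(path) -> list[DomainFeature]:
    """Read a domain-feature TSV (protein_id, feature_type, description,
    begin, end)."""
    import pandas as pd

    df = pd.read_csv(path, sep="\t", dtype=str)
    required = ("protein_id", "feature_type", "description", "begin", "end")
    for col in required:
        if col not in df.columns:
            raise ValueError(f"domain table {path} is missing column {col!r}")
    return [
        DomainFeature(
            r.protein_id, r.feature_type, r.description,
            int(r.begin), int(r.end),
        )
        for r in df.itertuples(index=False)
    ]


@dataclass(frozen=True)
class OrfBar:
    """One cORF to draw on the protein plot."""

    label: str
    residue_start: int | None  # 1-based inclusive; None = no parental anchor
    residue_end: int | None
    novel_n_aa: int
    novel_c_aa: int
    transcript_id: str


def protein_plot(
    parent_protein_length: int,
    domains: list[DomainFeature],
    orf_bars: list[OrfBar],
    out_path,
    colors: dict | None = None,
) -> TrackLayout:
    """Render the cORF-to-protein alignment view to SVG.

    The top row is the full-length protein with domain boxes and labels;
    each cORF is drawn below at its parental residue interval with hatched
    novel overhangs, filled by a per-source-transcript color assigned in
    order of first appearance.
    """
    for d in domains:
        if d.end > parent_protein_length:
            raise ValueError(
                f"domain [{d.begin}, {d.end}] outside protein of length "
                f"{parent_protein_length}"
            )
    palette = dict(COLORS)
    if colors:
        palette.update(colors)
    to_x = _scale(0, parent_protein_length)
    aa_w = (_W - 2 * _MARGIN) / max(parent_protein_length, 1)

    tx_color: dict[str, str] = {}
    for bar in orf_bars:
        if bar.transcript_id not in tx_color:
            tx_color[bar.transcript_id] = TRANSCRIPT_PALETTE[
                len(tx_color) % len(TRANSCRIPT_PALETTE)
            ]

    layout = TrackLayout()
    body = []
    y = 30.0
    body.append(_text(_MARGIN, y - 3, f"protein ({parent_protein_length} aa)"))
    layout.rows.append(
        ("protein", [(to_x(0), to_x(parent_protein_length))], "reference")
    )
    body.append(
        _rect(to_x(0), y, to_x(parent_protein_length) - to_x(0), _ROW_H,
              "#BBBBBB", "reference")
    )
    for d in sorted(domains, key=lambda d: (d.begin, d.end, d.description)):
        x0, x1 = to_x(d.begin - 1), to_x(d.end)
        layout.rows.append((d.description, [(x0, x1)], "domain"))
        body.append(
            _rect(x0, y - 2, max(x1 - x0, 1.0), _ROW_H + 4,
                  palette["domain"], "domain")
        )
        body.append(_text(x0, y - 6, d.description, size=8))
    y += _ROW_H + 3 * _ROW_GAP

    for bar in orf_bars:
        fill = tx_color[bar.transcript_id]
        if bar.residue_start is not None:
            x0, x1 = to_x(bar.residue_start - 1), to_x(bar.residue_end)
            if bar.novel_n_aa:
                body.append(
                    _rect(x0 - bar.novel_n_aa * aa_w, y + 2,
                          bar.novel_n_aa * aa_w, _ROW_H - 4,
                          "url(#hatch)", "orf_overhang")
                )
            body.append(
                _rect(x0, y, max(x1 - x0, 1.0), _ROW_H, fill, "orf_segment")
            )
            if bar.novel_c_aa:
                body.append(
                    _rect(x1, y + 2, bar.novel_c_aa * aa_w, _ROW_H - 4,
                          "url(#hatch)", "orf_overhang")
                )
            layout.rows.append((bar.label, [(x0, x1)], "orf_segment"))
            body.append(_text(x1 + 4, y + _ROW_H - 3, bar.label, size=8))
        else:
            # Unanchored ORF: a single hatched bar at the left margin.
            w = max(bar.novel_n_aa, 1) * aa_w
            body.append(
                _rect(to_x(0), y, w, _ROW_H, "url(#hatch)", "orf_overhang")
            )
            layout.rows.append((bar.label, [(to_x(0), to_x(0) + w)],
                                "orf_overhang"))
            body.append(_text(to_x(0) + w + 4, y + _ROW_H - 3, bar.label,
                              size=8))
        y += _ROW_H + _ROW_GAP

    height = y + 20
    svg = _svg_header(height) + "".join(body) + "</svg>\n"
    with open(out_path, "w") as fh:
        fh.write(svg)
    return layout
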