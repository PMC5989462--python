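"""Static Circos-style and linear synteny plots, plus a static HTML site.

All plots are emitted as deterministic standalone SVG text: the same inputs
always produce byte-identical documents, and stable CSS class names
(``chrom-arc``, ``ribbon``, ``quad``, ``bowtie``, ``gene``, ``gene-marker``,
``cytoband``, ``track``) make elements machine-countable.

The circular plot lays the reference chromosomes and each target genome's
chromosomes around one circle, arc sweep proportional to chromosome length
with a fixed gap angle between chromosomes, and draws one ribbon per
(block x target placement). The linear plot shows one reference chromosome
as a top track, one track per partner target chromosome below, and a
quadrilateral per block — drawn crossed ("bow-tie") when the placement is
inverted. Genes render as strand-colored rectangles (blue +, green -) and a
highlighted gene gets a red triangle at its midpoint. Raster/PDF export
rasterizes the SVG only when an optional backend (cairosvg) is importable;
SVG is the contract.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass, field
from pathlib import Path
from xml.sax.saxutils import escape

from .core import (
    Cytoband,
    Gene,
    Karyotype,
    SyntenyError,
    SyntenyMap,
    natural_chrom_key,
)

__all__ = [
    "PlotOptions",
    "render_circos",
    "render_linear",
    "save_plot",
    "export_site",
    "check_links",
]

# fixed categorical palette keyed by chromosome index (determinism over
# aesthetics; recycled when a genome has more chromosomes than entries)
PALETTE = [
    "#1f77b4", "#ff7f0e", "#2ca02c", "#d62728", "#9467bd", "#8c564b",
    "#e377c2", "#7f7f7f", "#bcbd22", "#17becf", "#393b79", "#637939",
    "#8c6d31", "#843c39", "#7b4173", "#3182bd", "#e6550d", "#31a354",
    "#756bb1", "#636363",
]

STAIN_FILL = {
    "gneg": "#ffffff", "gpos25": "#c8c8c8", "gpos50": "#969696",
    "gpos75": "#646464", "gpos100": "#323232", "acen": "#cc4444",
    "gvar": "#dddddd", "stalk": "#6688aa",
}

GENE_PLUS_FILL = "#2b6cb0"   # blue: forward-strand genes
GENE_MINUS_FILL = "#2f855a"  # green: reverse-strand genes


@dataclass
class PlotOptions:
    show_cytobands: bool = False
    highlight_chrom: str | None = None
    highlight_gene: str | None = None
    ribbon_color_by: str = "reference-chrom"  # or "target-chrom"
    image_formats: frozenset = field(default_factory=lambda: frozenset({"SVG"}))
    width: int = 900
    height: int = 900

    def __post_init__(self) -> None:
        if self.ribbon_color_by not in ("reference-chrom", "target-chrom"):
            raise SyntenyError(f"bad ribbon_color_by {self.ribbon_color_by!r}")
        bad = set(self.image_formats) - {"SVG", "PNG", "JPEG", "PDF"}
        if bad:
            raise SyntenyError(f"unsupported image formats {sorted(bad)}")


def _f(v: float) -> str:
    return f"{v:.3f}"


def _polar(cx: float, cy: float, r: float, deg: float) -> tuple[float, float]:
    rad = math.radians(deg)
    return cx + r * math.cos(rad), cy + r * math.sin(rad)


def _arc_path(cx, cy, r_out, r_in, a0, a1) -> str:
    """Annular sector path from angle a0 to a1 (degrees)."""
    large = 1 if (a1 - a0) > 180 else 0
    x0, y0 = _polar(cx, cy, r_out, a0)
    x1, y1 = _polar(cx, cy, r_out, a1)
    x2, y2 = _polar(cx, cy, r_in, a1)
    x3, y3 = _polar(cx, cy, r_in, a0)
    return (
        f"M {_f(x0)} {_f(y0)} "
        f"A {_f(r_out)} {_f(r_out)} 0 {large} 1 {_f(x1)} {_f(y1)} "
        f"L {_f(x2)} {_f(y2)} "
        f"A {_f(r_in)} {_f(r_in)} 0 {large} 0 {_f(x3)} {_f(y3)} Z"
    )


def _ribbon_path(cx, cy, r, ra0, ra1, rb0, rb1) -> str:
    """Ribbon from sub-arc [ra0, ra1] to sub-arc [rb0, rb1] at radius r,
    with quadratic beziers pulled toward the center."""
    ax0, ay0 = _polar(cx, cy, r, ra0)
    ax1, ay1 = _polar(cx, cy, r, ra1)
    bx0, by0 = _polar(cx, cy, r, rb0)
    bx1, by1 = _polar(cx, cy, r, rb1)
    return (
        f"M {_f(ax0)} {_f(ay0)} "
        f"A {_f(r)} {_f(r)} 0 0 1 {_f(ax1)} {_f(ay1)} "
        f"Q {_f(cx)} {_f(cy)} {_f(bx0)} {_f(by0)} "
        f"A {_f(r)} {_f(r)} 0 0 1 {_f(bx1)} {_f(by1)} "
        f"Q {_f(cx)} {_f(cy)} {_f(ax0)} {_f(ay0)} Z"
    )


class _CircosLayout:
    """Angular layout: every chromosome of every genome gets one sector,
    sweep proportional to bp, with a fixed gap angle between sectors."""

    GAP_DEG = 2.0

    def __init__(self, genomes: list[tuple[str, Karyotype]]):
        total_bp = sum(k.total_length for _, k in genomes)
        n_sectors = sum(len(k.chromosomes) for _, k in genomes)
        usable = 360.0 - n_sectors * self.GAP_DEG
        if usable <= 0:
            raise SyntenyError("too many chromosomes for the fixed gap angle")
        self.sectors: dict[tuple[str, str], tuple[float, float]] = {}
        angle = -90.0  # start at 12 o'clock
        for genome, karyotype in genomes:
            for name, length in karyotype.chromosomes:
                sweep = usable * length / total_bp
                self.sectors[(genome, name)] = (angle, sweep)
                angle += sweep + self.GAP_DEG

    def angle_of(self, genome: str, chrom: str, pos: int, length: int) -> float:
        a0, sweep = self.sectors[(genome, chrom)]
        return a0 + sweep * pos / length


def render_circos(
    smap: SyntenyMap,
    ref_karyotype: Karyotype,
    tgt_karyotypes: dict[str, Karyotype],
    cytobands: dict[str, list[Cytoband]] | None = None,
    options: PlotOptions | None = None,
) -> str:
    """Render the whole-genome circular synteny plot as SVG text."""
    opt = options or PlotOptions()
    if not smap.blocks:
        raise SyntenyError("cannot render a circular plot for an empty map")
    missing = [t for t in smap.targets if t not in tgt_karyotypes]
    if missing:
        raise SyntenyError(f"no karyotype provided for targets {missing}")
    all_chroms = set(ref_karyotype.names)
    for k in tgt_karyotypes.values():
        all_chroms.update(k.names)
    if opt.highlight_chrom is not None and opt.highlight_chrom not in all_chroms:
        raise SyntenyError(f"unknown highlight chromosome {opt.highlight_chrom!r}")

    genomes = [(smap.reference, ref_karyotype)] + [
        (t, tgt_karyotypes[t]) for t in smap.targets
    ]
    layout = _CircosLayout(genomes)
    W, H = opt.width, opt.height
    cx, cy = W / 2, H / 2
    r_out = 0.46 * min(W, H)
    r_in = r_out - 18
    r_band = r_in - 10
    r_ribbon = r_band - 4 if (opt.show_cytobands and cytobands) else r_in - 4

    parts: list[str] = [
        f'<svg xmlns="http://www.w3.org/2000/svg" width="{W}" height="{H}" '
        f'viewBox="0 0 {W} {H}">',
        f'<rect width="{W}" height="{H}" fill="#ffffff"/>',
    ]

    # chromosome arcs with sweep metadata
    for genome, karyotype in genomes:
        for ci, (name, length) in enumerate(karyotype.chromosomes):
            a0, sweep = layout.sectors[(genome, name)]
            color = PALETTE[ci % len(PALETTE)]
            parts.append(
                f'<path class="chrom-arc" data-genome="{escape(genome)}" '
                f'data-chrom="{escape(name)}" data-sweep="{sweep:.4f}" '
                f'd="{_arc_path(cx, cy, r_out, r_in, a0, a0 + sweep)}" '
                f'fill="{color}" stroke="#333333" stroke-width="0.5"/>'
            )
            mx, my = _polar(cx, cy, r_out + 12, a0 + sweep / 2)
            parts.append(
                f'<text class="chrom-label" x="{_f(mx)}" y="{_f(my)}" '
                f'font-size="9" text-anchor="middle">{escape(name)}</text>'
            )

    # optional cytoband ring
    if opt.show_cytobands and cytobands:
        for genome, karyotype in genomes:
            for band in cytobands.get(genome, []):
                if band.location.chrom not in karyotype:
                    continue
                length = karyotype.length_of(band.location.chrom)
                a0 = layout.angle_of(genome, band.location.chrom, band.location.start, length)
                a1 = layout.angle_of(genome, band.location.chrom, band.location.end, length)
                fill = STAIN_FILL.get(band.stain, "#eeeeee")
                parts.append(
                    f'<path class="cytoband" data-stain="{escape(band.stain)}" '
                    f'd="{_arc_path(cx, cy, r_in - 2, r_band, a0, a1)}" '
                    f'fill="{fill}" stroke="#999999" stroke-width="0.25"/>'
                )

    # ribbons: one per (block x target placement)
    for b in smap.blocks:
        ref_len = ref_karyotype.length_of(b.ref.chrom)
        ra0 = layout.angle_of(smap.reference, b.ref.chrom, b.ref.start, ref_len)
        ra1 = layout.angle_of(smap.reference, b.ref.chrom, b.ref.end, ref_len)
        for tgt_genome in smap.targets:
            if tgt_genome not in b.placements:
                continue
            pl = b.placements[tgt_genome]
            karyotype = tgt_karyotypes[tgt_genome]
            tgt_len = karyotype.length_of(pl.tgt.chrom)
            rb0 = layout.angle_of(tgt_genome, pl.tgt.chrom, pl.tgt.start, tgt_len)
            rb1 = layout.angle_of(tgt_genome, pl.tgt.chrom, pl.tgt.end, tgt_len)
            if opt.ribbon_color_by == "reference-chrom":
                color = PALETTE[ref_karyotype.order_index(b.ref.chrom) % len(PALETTE)]
            else:
                color = PALETTE[karyotype.order_index(pl.tgt.chrom) % len(PALETTE)]
            if opt.highlight_chrom is None:
                opacity = 0.55
            else:
                incident = opt.highlight_chrom in (b.ref.chrom, pl.tgt.chrom)
                opacity = 0.75 if incident else 0.08
            parts.append(
                f'<path class="ribbon" data-block="{b.block_id}" '
                f'data-target="{escape(tgt_genome)}" '
                f'd="{_ribbon_path(cx, cy, r_ribbon, ra0, ra1, rb0, rb1)}" '
                f'fill="{color}" fill-opacity="{opacity}" stroke="none"/>'
            )

    parts.append("</svg>")
    return "\n".join(parts) + "\n"


def render_linear(
    smap: SyntenyMap,
    ref_chrom: str,
    target: str,
    genes: list[Gene] | None = None,
    ref_karyotype: Karyotype | None = None,
    tgt_karyotype: Karyotype | None = None,
    options: PlotOptions | None = None,
) -> str:
    """Render the linear browser-style plot for one reference chromosome
    against one target genome, as SVG text.

    Each track is scaled so the whole chromosome fills the plot width, so a
    drawn span's width over the track width equals its bp span over the
    chromosome length. Per-block coordinates are embedded as ``<title>``
    text on each quadrilateral.
    """
    opt = options or PlotOptions()
    blocks = [b for b in smap.blocks_for(target) if b.ref.chrom == ref_chrom]
    if not blocks:
        raise SyntenyError(f"no blocks on {ref_chrom!r} for target {target!r}")
    W = opt.width
    margin = 60
    track_w = W - 2 * margin
    track_h = 14

    ref_len = (ref_karyotype.length_of(ref_chrom) if ref_karyotype
               else max(b.ref.end for b in blocks))
    partner_chroms = sorted(
        {b.placements[target].tgt.chrom for b in blocks}, key=natural_chrom_key
    )
    tgt_lens = {}
    for chrom in partner_chroms:
        if tgt_karyotype is not None and chrom in tgt_karyotype:
            tgt_lens[chrom] = tgt_karyotype.length_of(chrom)
        else:
            tgt_lens[chrom] = max(
                b.placements[target].tgt.end for b in blocks
                if b.placements[target].tgt.chrom == chrom
            )

    gene_rows = [g for g in (genes or []) if g.location.chrom == ref_chrom]
    ref_y = 60
    gene_y = ref_y + track_h + 8
    gene_h = 10 if gene_rows else 0
    first_tgt_y = gene_y + gene_h + 90
    row_step = 80
    H = first_tgt_y + row_step * len(partner_chroms)

    def ref_x(pos: int) -> float:
        return margin + track_w * pos / ref_len

    parts = [
        f'<svg xmlns="http://www.w3.org/2000/svg" width="{W}" height="{H}" '
        f'viewBox="0 0 {W} {H}">',
        f'<rect width="{W}" height="{H}" fill="#ffffff"/>',
        f'<text x="{margin}" y="20" font-size="13">{escape(smap.reference)}.{escape(ref_chrom)}'
        f' vs {escape(target)}</text>',
        f'<rect class="track track-ref" data-chrom="{escape(ref_chrom)}" '
        f'data-length="{ref_len}" x="{margin}" y="{ref_y}" '
        f'width="{track_w}" height="{track_h}" fill="#d9d9d9" stroke="#333333"/>',
    ]

    # gene annotation track: blue forward, green reverse
    for g in gene_rows:
        x0, x1 = ref_x(g.location.start), ref_x(g.location.end)
        fill = GENE_PLUS_FILL if g.strand == "+" else GENE_MINUS_FILL
        cls = "gene gene-plus" if g.strand == "+" else "gene gene-minus"
        parts.append(
            f'<rect class="{cls}" data-name="{escape(g.name)}" x="{_f(x0)}" '
            f'y="{gene_y}" width="{_f(max(x1 - x0, 0.5))}" height="{gene_h}" '
            f'fill="{fill}"><title>{escape(g.name)} ({g.strand})</title></rect>'
        )
    if opt.highlight_gene is not None:
        marked = [g for g in gene_rows if g.name == opt.highlight_gene]
        if not marked:
            raise SyntenyError(f"highlight gene {opt.highlight_gene!r} not on {ref_chrom!r}")
        g = marked[0]
        mid = ref_x((g.location.start + g.location.end) // 2)
        ty = gene_y + gene_h + 2
        parts.append(
            f'<polygon class="gene-marker" data-name="{escape(g.name)}" '
            f'points="{_f(mid)},{ty} {_f(mid - 5)},{ty + 9} {_f(mid + 5)},{ty + 9}" '
            f'fill="#cc0000"/>'
        )

    # target tracks and block quadrilaterals
    for row, chrom in enumerate(partner_chroms):
        ty = first_tgt_y + row * row_step
        tlen = tgt_lens[chrom]

        def tgt_x(pos: int) -> float:
            return margin + track_w * pos / tlen

        parts.append(
            f'<rect class="track track-tgt" data-chrom="{escape(chrom)}" '
            f'data-length="{tlen}" x="{margin}" y="{ty}" width="{track_w}" '
            f'height="{track_h}" fill="#d9d9d9" stroke="#333333"/>'
        )
        parts.append(
            f'<text class="track-label" x="{margin}" y="{ty + track_h + 12}" '
            f'font-size="10">{escape(target)}.{escape(chrom)}</text>'
        )
        y_top = ref_y + track_h
        for b in blocks:
            pl = b.placements[target]
            if pl.tgt.chrom != chrom:
                continue
            rx0, rx1 = ref_x(b.ref.start), ref_x(b.ref.end)
            tx0, tx1 = tgt_x(pl.tgt.start), tgt_x(pl.tgt.end)
            color = PALETTE[b.block_id % len(PALETTE)]
            if pl.orientation == "+":
                pts = f"{_f(rx0)},{y_top} {_f(rx1)},{y_top} {_f(tx1)},{ty} {_f(tx0)},{ty}"
                cls = "quad"
            else:
                # crossed edges mark an inverted placement
                pts = f"{_f(rx0)},{y_top} {_f(rx1)},{y_top} {_f(tx0)},{ty} {_f(tx1)},{ty}"
                cls = "quad bowtie"
            coords = (
                f"block {b.block_id}: {smap.reference}.{b.ref.chrom}"
                f":{b.ref.start + 1}-{b.ref.end} + | {target}.{pl.tgt.chrom}"
                f":{pl.tgt.start + 1}-{pl.tgt.end} {pl.orientation}"
            )
            parts.append(
                f'<polygon class="{cls}" data-block="{b.block_id}" points="{pts}" '
                f'fill="{color}" fill-opacity="0.45" stroke="#555555" '
                f'stroke-width="0.5"><title>{escape(coords)}</title></polygon>'
            )

    parts.append("</svg>")
    return "\n".join(parts) + "\n"


def save_plot(svg_text: str, basepath: str | Path, options: PlotOptions | None = None) -> list[Path]:
    """Write the SVG (always) and any requested raster/PDF renditions next
    to it. Raster formats need the optional cairosvg backend; without it a
    RuntimeError names the missing piece."""
    opt = options or PlotOptions()
    base = Path(basepath)
    base.parent.mkdir(parents=True, exist_ok=True)
    written = []
    svg_path = base.with_suffix(".svg")
    svg_path.write_text(svg_text)
    written.append(svg_path)
    extra = set(opt.image_formats) - {"SVG"}
    if extra:
        try:
            import cairosvg  # optional raster backend
        except ImportError as exc:
            raise RuntimeError(
                "PNG/JPEG/PDF export needs the optional cairosvg backend; "
                "only SVG was written"
            ) from exc
        for fmt in sorted(extra):
            out = base.with_suffix("." + fmt.lower())
            if fmt == "PNG":
                cairosvg.svg2png(bytestring=svg_text.encode(), write_to=str(out))
            elif fmt == "PDF":
                cairosvg.svg2pdf(bytestring=svg_text.encode(), write_to=str(out))
            else:  # JPEG via PNG + pillow
                from io import BytesIO
                from PIL import Image
                png = cairosvg.svg2png(bytestring=svg_text.encode())
                Image.open(BytesIO(png)).convert("RGB").save(out, "JPEG")
            written.append(out)
    return written


# ---------------------------------------------------------------------------
# static site export


_PAGE = """<!DOCTYPE html>
<html>
<head>
<meta charset="utf-8"/>
<title>{title}</title>
<style>
body {{ font-family: sans-serif; margin: 1.5em; }}
nav a {{ margin-right: 1em; }}
</style>
</head>
<body>
<nav><a href="index.html">index</a><a href="circos.html">circos</a></nav>
<h1>{title}</h1>
{body}
</body>
</html>
"""


def export_site(
    smap: SyntenyMap,
    ref_karyotype: Karyotype,
    tgt_karyotypes: dict[str, Karyotype],
    genes: list[Gene] | None = None,
    cytobands: dict[str, list[Cytoband]] | None = None,
    out_dir: str | Path = "site",
    options: PlotOptions | None = None,
) -> list[Path]:
    """Write a static HTML tree: one index page, one circular-plot page,
    and one linear-plot page per (reference chromosome x target). File
    names are deterministic (``circos.html``,
    ``browser_<refchrom>_<target>.html``) and regeneration is
    byte-identical. Returns the written pages."""
    if not smap.blocks:
        raise SyntenyError("cannot export a site for an empty map")
    opt = options or PlotOptions()
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    pages: list[Path] = []

    browser_pages: list[tuple[str, str, str]] = []  # (fname, chrom, target)
    for chrom in ref_karyotype.names:
        for target in smap.targets:
            browser_pages.append((f"browser_{chrom}_{target}.html", chrom, target))

    links = "\n".join(
        f'<li><a href="{fname}">{chrom} vs {escape(t)}</a></li>'
        for fname, chrom, t in browser_pages
    )
    index_body = (
        f"<p>Reference genome: <b>{escape(smap.reference)}</b>; targets: "
        f"{escape(', '.join(smap.targets))}; {len(smap.blocks)} synteny blocks.</p>"
        f'<p><a href="circos.html">Whole-genome circular plot</a></p>'
        f"<ul>\n{links}\n</ul>"
    )
    index = out / "index.html"
    index.write_text(_PAGE.format(title=f"{smap.reference} synteny", body=index_body))
    pages.append(index)

    circos_svg = render_circos(smap, ref_karyotype, tgt_karyotypes, cytobands, opt)
    circos = out / "circos.html"
    circos.write_text(_PAGE.format(title=f"{smap.reference} circular synteny plot",
                                   body=circos_svg))
    pages.append(circos)

    for fname, chrom, target in browser_pages:
        has_blocks = any(
            b.ref.chrom == chrom and target in b.placements for b in smap.blocks
        )
        if has_blocks:
            body = render_linear(
                smap, chrom, target, genes=genes,
                ref_karyotype=ref_karyotype,
                tgt_karyotype=tgt_karyotypes.get(target),
                options=opt,
            )
        else:
            body = f"<p>No synteny blocks on {escape(chrom)} for {escape(target)}.</p>"
        page = out / fname
        page.write_text(_PAGE.format(title=f"{chrom} vs {target}", body=body))
        pages.append(page)
    return pages


_HREF = re.compile(r'href="([^"#]+)"')


def check_links(out_dir: str | Path) -> bool:
    """Verify every relative href in the generated tree resolves to a file;
    raises on the first broken link."""
    out = Path(out_dir)
    for page in sorted(out.glob("*.html")):
        for href in _HREF.findall(page.read_text()):
            if href.startswith(("http:", "https:", "mailto:")):
                continue
            if not (out / href).exists():
                raise SyntenyError(f"{page.name}: broken link to {href}")
    return True
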