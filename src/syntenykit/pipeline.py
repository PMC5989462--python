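"""Build-directory pipeline: INI configuration, database build, analysis.

A build is described by an INI file::

    [reference]
    name = hg
    sizes = hg.chrom.sizes
    genes = hg.genes.bed          ; optional
    cytoband = hg.cytoband.txt    ; optional

    [target:mm]
    sizes = mm.chrom.sizes
    chain = hg.mm.chain           ; exactly one of chain / anchors / synteny
    ; anchors = hg.mm.anchors.tsv
    ; synteny = hg.mm.blocks.tsv
    ; dialect = generic           ; for anchors/synteny sources

    [params]
    resolution = 150000
    max_gap = 150000              ; optional, defaults to resolution
    min_anchor = 100              ; optional

    [output]
    dir = build_hg

Building writes, into the output directory: copies of the input chrom.sizes
(and genes/cytoband) files so later steps need nothing outside the
directory, one unified pairwise synteny file per target, the multi-species
unified file (intersection across all targets), the analysis TSVs, and a
``manifest.json`` recording parameters and SHA-256 digests of all inputs
and outputs. Re-running an unchanged config is byte-identical, and several
configs build independent directories side by side.
"""

from __future__ import annotations

import configparser
import hashlib
import json
import shutil
from dataclasses import dataclass, field
from pathlib import Path

from . import analysis, build, io, viz
from .core import BuildParams, Karyotype, SyntenyError, SyntenyMap

__all__ = [
    "GenomeEntry",
    "TargetEntry",
    "BuildConfig",
    "parse_build_config",
    "run_build",
    "run_analyze",
    "run_plot",
    "run_site",
]

DEFAULT_RESOLUTION = 150_000


@dataclass
class GenomeEntry:
    name: str
    sizes: Path
    genes: Path | None = None
    cytoband: Path | None = None


@dataclass
class TargetEntry(GenomeEntry):
    source_kind: str = "chain"  # chain | anchors | synteny
    source_path: Path = None  # type: ignore[assignment]
    dialect: str = "generic"


@dataclass
class BuildConfig:
    reference: GenomeEntry
    targets: list[TargetEntry]
    params: BuildParams
    out_dir: Path
    config_path: Path | None = None


def _require(section, key, path, name):
    if key not in section:
        raise SyntenyError(f"{path}: section [{name}] is missing required key {key!r}")
    return section[key]


def parse_build_config(path: str | Path) -> BuildConfig:
    path = Path(path)
    cp = configparser.ConfigParser(inline_comment_prefixes=(";", "#"))
    try:
        with open(path) as fh:
            cp.read_file(fh, source=str(path))
    except configparser.Error as exc:
        raise SyntenyError(f"config parse error: {exc}") from exc

    if "reference" not in cp:
        raise SyntenyError(f"{path}: missing required section [reference]")
    ref_sec = cp["reference"]
    base = path.parent

    def respath(v: str) -> Path:
        p = Path(v)
        return p if p.is_absolute() else base / p

    reference = GenomeEntry(
        name=_require(ref_sec, "name", path, "reference"),
        sizes=respath(_require(ref_sec, "sizes", path, "reference")),
        genes=respath(ref_sec["genes"]) if "genes" in ref_sec else None,
        cytoband=respath(ref_sec["cytoband"]) if "cytoband" in ref_sec else None,
    )

    targets: list[TargetEntry] = []
    for section in cp.sections():
        if not section.startswith("target:"):
            continue
        name = section.split(":", 1)[1]
        sec = cp[section]
        sources = [k for k in ("chain", "anchors", "synteny") if k in sec]
        if len(sources) != 1:
            raise SyntenyError(
                f"{path}: [{section}] must declare exactly one of chain/anchors/synteny"
            )
        targets.append(
            TargetEntry(
                name=name,
                sizes=respath(_require(sec, "sizes", path, section)),
                genes=respath(sec["genes"]) if "genes" in sec else None,
                cytoband=respath(sec["cytoband"]) if "cytoband" in sec else None,
                source_kind=sources[0],
                source_path=respath(sec[sources[0]]),
                dialect=sec.get("dialect", "generic"),
            )
        )
    if not targets:
        raise SyntenyError(f"{path}: no [target:<name>] section found")

    params_sec = cp["params"] if "params" in cp else {}
    params = BuildParams(
        resolution=int(params_sec.get("resolution", DEFAULT_RESOLUTION)),
        max_gap=int(params_sec["max_gap"]) if "max_gap" in params_sec else None,
        min_anchor=int(params_sec.get("min_anchor", 100)),
    )
    out_sec = cp["output"] if "output" in cp else {}
    out_dir = respath(out_sec.get("dir", "build"))
    cfg = BuildConfig(reference, targets, params, out_dir, config_path=path)

    for entry in [cfg.reference, *cfg.targets]:
        for p in (entry.sizes, entry.genes, entry.cytoband,
                  getattr(entry, "source_path", None)):
            if p is not None and not Path(p).exists():
                raise SyntenyError(f"{path}: input file not found: {p}")
    return cfg


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def _load_anchors(target: TargetEntry, tgt_karyotype: Karyotype):
    if target.source_kind == "chain":
        return io.read_chain(target.source_path, tgt_karyotype)
    return io.read_anchors_tsv(target.source_path, target.dialect)


def run_build(config: BuildConfig) -> Path:
    """Execute a full build into the configured output directory and return
    its path."""
    out = config.out_dir
    out.mkdir(parents=True, exist_ok=True)
    ref_kt = io.read_chrom_sizes(config.reference.sizes, config.reference.name)

    inputs: dict[str, str] = {str(config.reference.sizes): _sha256(config.reference.sizes)}
    outputs: list[Path] = []

    # copy inputs in so downstream steps only need the build directory
    def stage(src: Path | None, dest_name: str) -> Path | None:
        if src is None:
            return None
        dest = out / dest_name
        shutil.copyfile(src, dest)
        inputs[str(src)] = _sha256(src)
        outputs.append(dest)
        return dest

    stage(config.reference.sizes, f"{config.reference.name}.sizes")
    stage(config.reference.genes, f"{config.reference.name}.genes.bed")
    stage(config.reference.cytoband, f"{config.reference.name}.cytoband.txt")

    pairwise: list[SyntenyMap] = []
    for target in config.targets:
        tgt_kt = io.read_chrom_sizes(target.sizes, target.name)
        stage(target.sizes, f"{target.name}.sizes")
        stage(target.cytoband, f"{target.name}.cytoband.txt")
        inputs[str(target.source_path)] = _sha256(target.source_path)
        if target.source_kind == "synteny":
            smap = io.convert_third_party(
                target.source_path, target.dialect,
                reference=config.reference.name, target=target.name,
                ref_karyotype=ref_kt,
            )
        else:
            anchors = _load_anchors(target, tgt_kt)
            smap = build.build_pairwise(
                anchors, config.reference.name, target.name, config.params,
                ref_karyotype=ref_kt,
            )
        smap.validate(ref_kt)
        dest = out / f"pairwise_{target.name}.synteny"
        io.write_unified(smap, dest)
        outputs.append(dest)
        pairwise.append(smap)

    multi = build.intersect_maps(pairwise, config.params)
    multi_path = out / "multi.synteny"
    io.write_unified(multi, multi_path)
    outputs.append(multi_path)

    outputs.extend(_write_reports(out, config.reference.name, ref_kt, pairwise))

    manifest = {
        "reference": config.reference.name,
        "targets": [t.name for t in config.targets],
        "params": {
            "resolution": config.params.resolution,
            "max_gap": config.params.max_gap,
            "min_anchor": config.params.min_anchor,
        },
        "pairwise_maps": [f"pairwise_{t.name}.synteny" for t in config.targets],
        "multi_map": "multi.synteny",
        "inputs": dict(sorted(inputs.items())),
        "outputs": {p.name: _sha256(p) for p in sorted(outputs)},
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    return out


def _write_reports(out: Path, ref_name: str, ref_kt: Karyotype,
                   pairwise: list[SyntenyMap]) -> list[Path]:
    written: list[Path] = []
    genes_path = out / f"{ref_name}.genes.bed"
    genes = io.read_bed_genes(genes_path) if genes_path.exists() else None
    for smap in pairwise:
        (target,) = smap.targets
        reports = [
            analysis.classify_chromosome(smap, chrom, target)
            for chrom in ref_kt.names
        ]
        p = out / f"chromosomes_{target}.tsv"
        analysis.write_chromosome_report_tsv(reports, p)
        written.append(p)
        cov = analysis.coverage_summary(smap, ref_kt)
        p = out / f"coverage_{target}.tsv"
        analysis.write_coverage_tsv(cov, p)
        written.append(p)
        if genes is not None:
            gc = analysis.classify_genes(genes, smap, target)
            p = out / f"genes_{target}.tsv"
            analysis.write_gene_report_tsv(gc, target, p)
            written.append(p)
    return written


def _read_manifest(build_dir: Path) -> dict:
    mpath = Path(build_dir) / "manifest.json"
    if not mpath.exists():
        raise SyntenyError(f"{build_dir} is not a build directory (no manifest.json)")
    return json.loads(mpath.read_text())


def _load_build(build_dir: str | Path):
    build_dir = Path(build_dir)
    m = _read_manifest(build_dir)
    ref_name = m["reference"]
    ref_kt = io.read_chrom_sizes(build_dir / f"{ref_name}.sizes", ref_name)
    tgt_kts = {
        t: io.read_chrom_sizes(build_dir / f"{t}.sizes", t) for t in m["targets"]
    }
    maps = {
        t: io.read_unified(build_dir / f"pairwise_{t}.synteny") for t in m["targets"]
    }
    multi = io.read_unified(build_dir / "multi.synteny")
    genes_path = build_dir / f"{ref_name}.genes.bed"
    genes = io.read_bed_genes(genes_path) if genes_path.exists() else None
    return m, ref_kt, tgt_kts, maps, multi, genes


def run_analyze(build_dir: str | Path, target: str) -> list[Path]:
    """Re-generate the analysis TSVs for one target of a built directory."""
    build_dir = Path(build_dir)
    m, ref_kt, _, maps, _, genes = _load_build(build_dir)
    if target not in maps:
        raise SyntenyError(f"unknown target {target!r}; built targets: {m['targets']}")
    smap = maps[target]
    written = []
    reports = [analysis.classify_chromosome(smap, c, target) for c in ref_kt.names]
    p = build_dir / f"chromosomes_{target}.tsv"
    analysis.write_chromosome_report_tsv(reports, p)
    written.append(p)
    p = build_dir / f"coverage_{target}.tsv"
    analysis.write_coverage_tsv(analysis.coverage_summary(smap, ref_kt), p)
    written.append(p)
    if genes is not None:
        p = build_dir / f"genes_{target}.tsv"
        analysis.write_gene_report_tsv(analysis.classify_genes(genes, smap, target), target, p)
        written.append(p)
    return written


def run_plot(
    build_dir: str | Path,
    ref_chrom: str | None = None,
    target: str | None = None,
    options: viz.PlotOptions | None = None,
) -> list[Path]:
    """Render plots from a built directory into ``<build_dir>/plots``:
    the multi-species circular plot, plus the linear plot when a reference
    chromosome and target are selected."""
    build_dir = Path(build_dir)
    _, ref_kt, tgt_kts, maps, multi, genes = _load_build(build_dir)
    plots = build_dir / "plots"
    plots.mkdir(exist_ok=True)
    opt = options or viz.PlotOptions()
    cytobands = _load_cytobands(build_dir, [ref_kt.genome_name, *tgt_kts])
    written = []
    svg = viz.render_circos(multi if multi.blocks else next(iter(maps.values())),
                            ref_kt, tgt_kts, cytobands, opt)
    written += viz.save_plot(svg, plots / "circos", opt)
    if ref_chrom is not None:
        if target is None:
            raise SyntenyError("linear plots need both --ref-chrom and --target")
        svg = viz.render_linear(maps[target], ref_chrom, target, genes=genes,
                                ref_karyotype=ref_kt, tgt_karyotype=tgt_kts[target],
                                options=opt)
        written += viz.save_plot(svg, plots / f"linear_{ref_chrom}_{target}", opt)
    return written


def _load_cytobands(build_dir: Path, genomes) -> dict:
    out = {}
    for g in genomes:
        p = build_dir / f"{g}.cytoband.txt"
        if p.exists():
            out[g] = io.read_cytoband(p)
    return out


def run_site(build_dir: str | Path, options: viz.PlotOptions | None = None) -> list[Path]:
    """Export the static HTML site of a built directory into
    ``<build_dir>/site`` (circular page, one linear page per reference
    chromosome x target, index)."""
    build_dir = Path(build_dir)
    _, ref_kt, tgt_kts, maps, multi, genes = _load_build(build_dir)
    # linear pages draw from the pairwise maps; merge them for the site
    merged = _merge_pairwise(maps)
    cytobands = _load_cytobands(build_dir, [ref_kt.genome_name, *tgt_kts])
    pages = viz.export_site(
        merged, ref_kt, tgt_kts, genes=genes, cytobands=cytobands,
        out_dir=build_dir / "site", options=options,
    )
    viz.check_links(build_dir / "site")
    return pages


def _merge_pairwise(maps: dict[str, SyntenyMap]) -> SyntenyMap:
    """Concatenate pairwise maps into one display map (block ids renumbered;
    reference intervals of different targets may overlap, so this is for
    rendering only)."""
    targets = list(maps)
    first = maps[targets[0]]
    blocks = []
    for t in targets:
        for b in maps[t].blocks:
            blocks.append(type(b)(len(blocks) + 1, b.ref, dict(b.placements)))
    out = SyntenyMap(reference=first.reference, targets=targets, blocks=blocks,
                     resolution=first.resolution)
    out.sort_blocks()
    out.renumber()
    return out
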