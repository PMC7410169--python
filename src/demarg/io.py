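"""Readers, writers and the compressed-alignment container.

Site compression: the window is cut at every variant position; each variant
position becomes its own width-1 column, and the invariant stretches between
variants are chunked into columns of at most ``compress`` bases.  Total base
counts are conserved exactly.  An invariant column's substitution rate is its
per-site rate times its width; a variant column keeps one representative
site.

The *sites* dialect used here is a plain-text tab-separated format::

    #NAMES  lin1  lin2  ...          (one column per haploid lineage)
    #REGION chrom  start  end        (1-based, end inclusive)
    position  AACCN...               (1-based position; one base per lineage,
                                      N = missing)

Only variant positions are listed; everything between them is invariant.
Missing data is 'N'; masking is applied explicitly through BED intervals.
"""

from __future__ import annotations

import io as _io
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import yaml

from .demography import (
    DemographicModel,
    MigrationBand,
    Population,
    SampleConfig,
    build_time_grid,
)
from .threading import EmissionContext

__all__ = [
    "CompressedAlignment",
    "compress_alignment",
    "load_alignment",
    "read_sites",
    "write_sites",
    "read_bed",
    "load_model",
    "dump_model",
    "write_calls_bed",
    "read_calls_bed",
    "write_bedgraph",
    "write_stats",
    "write_arg_sample",
]

DEFAULT_MU = 1.45e-8  # per generation per site


@dataclass
class CompressedAlignment:
    """Genotype matrix over compressed columns plus the column -> bp map."""

    alleles: np.ndarray          # (n_lineages, L) int8: 0/1/-1
    widths: np.ndarray           # (L,) int, bases represented
    starts: np.ndarray           # (L,) int, bp start (0-based) of each column
    variant: np.ndarray          # (L,) bool
    mu_site: np.ndarray          # (L,) per-site per-generation rate
    window_bp: int
    lineage_names: list[str]
    chrom: str = "chr"
    offset: int = 0              # bp coordinate of window start
    n_dropped: int = 0           # multi-allelic sites discarded at load

    @property
    def L(self) -> int:
        return len(self.widths)

    @property
    def mu_eff(self) -> np.ndarray:
        return np.where(self.variant, self.mu_site, self.mu_site * self.widths)

    @property
    def ctx(self) -> EmissionContext:
        return EmissionContext(
            alleles=self.alleles,
            mu_eff=self.mu_eff.astype(float),
            widths=self.widths.astype(float),
        )

    def col_to_bp(self, col: int) -> int:
        return self.offset + int(self.starts[col])

    def cols_to_bp(self, start_col: int, end_col: int) -> tuple[int, int]:
        end = self.window_bp if end_col >= self.L else int(self.starts[end_col])
        return self.offset + int(self.starts[start_col]), self.offset + end


def _mu_lookup(mu, pos: np.ndarray) -> np.ndarray:
    """Per-site rate at positions; ``mu`` is a scalar or (breaks, rates)."""
    if np.isscalar(mu):
        return np.full(len(pos), float(mu))
    breaks, rates = mu
    idx = np.clip(np.searchsorted(breaks, pos, side="right") - 1, 0, len(rates) - 1)
    return np.asarray(rates, dtype=float)[idx]


def _mask_bitmaps(masks, lineage_names, samples: Sequence[SampleConfig],
                  window_bp: int) -> Optional[np.ndarray]:
    if not masks:
        return None
    bm = np.zeros((len(lineage_names), window_bp), dtype=bool)
    by_sample = {s.sample_id: s for s in samples} if samples else {}
    for key, ivals in masks.items():
        rows = []
        if key in lineage_names:
            rows = [lineage_names.index(key)]
        elif key in by_sample:
            rows = [lineage_names.index(n) for n in by_sample[key].lineages]
        else:
            raise KeyError(f"mask key {key!r} matches no sample or lineage")
        for a, b in ivals:
            a, b = max(0, int(a)), min(window_bp, int(b))
            for r in rows:
                bm[r, a:b] = True
    return bm


def compress_alignment(
    positions: np.ndarray,
    site_alleles: np.ndarray,
    window_bp: int,
    lineage_names: list[str],
    compress: int = 10,
    mu=DEFAULT_MU,
    masks=None,
    samples: Sequence[SampleConfig] = (),
    chrom: str = "chr",
    offset: int = 0,
    n_dropped: int = 0,
) -> CompressedAlignment:
    """Build compressed columns from variant sites over a window.

    ``positions`` are 0-based variant positions; ``site_alleles`` is
    (n_lineages, n_sites) with 0/1/-1.  A lineage is missing in an invariant
    column when more than half of the column's bases are masked for it.
    """
    positions = np.asarray(positions, dtype=np.int64)
    order = np.argsort(positions)
    positions = positions[order]
    site_alleles = np.asarray(site_alleles, dtype=np.int8)[:, order]
    n = len(lineage_names)
    bm = _mask_bitmaps(masks, lineage_names, samples, window_bp)

    col_start, col_width, col_var = [], [], []
    col_alleles = []
    cursor = 0

    def add_invariant(a: int, b: int):
        nonlocal cursor
        pos = a
        while pos < b:
            w = min(compress, b - pos)
            col_start.append(pos)
            col_width.append(w)
            col_var.append(False)
            if bm is None:
                col_alleles.append(np.zeros(n, dtype=np.int8))
            else:
                frac = bm[:, pos:pos + w].mean(axis=1)
                col_alleles.append(np.where(frac > 0.5, -1, 0).astype(np.int8))
            pos += w

    for k, p in enumerate(positions):
        if p >= window_bp or p < 0:
            raise ValueError(f"variant position {p} outside window [0, {window_bp})")
        if p > cursor:
            add_invariant(cursor, int(p))
        col_start.append(int(p))
        col_width.append(1)
        col_var.append(True)
        a = site_alleles[:, k].copy()
        if bm is not None:
            a[bm[:, p]] = -1
        col_alleles.append(a)
        cursor = int(p) + 1
    if cursor < window_bp:
        add_invariant(cursor, window_bp)

    starts = np.asarray(col_start, dtype=np.int64)
    widths = np.asarray(col_width, dtype=np.int64)
    mids = starts + widths // 2
    return CompressedAlignment(
        alleles=np.stack(col_alleles, axis=1),
        widths=widths,
        starts=starts,
        variant=np.asarray(col_var, dtype=bool),
        mu_site=_mu_lookup(mu, mids),
        window_bp=int(window_bp),
        lineage_names=list(lineage_names),
        chrom=chrom,
        offset=int(offset),
        n_dropped=n_dropped,
    )


# ------------------------------------------------------------------ #
# sites format
# ------------------------------------------------------------------ #

def read_sites(path_or_buf):
    """Parse the sites dialect; returns (names, chrom, start, end, positions,
    allele strings).  Positions are converted to 0-based window offsets."""
    close = False
    if isinstance(path_or_buf, (str, bytes)):
        fh = open(path_or_buf)
        close = True
    else:
        fh = path_or_buf
    names = None
    region = None
    positions, rows = [], []
    try:
        for ln, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line:
                continue
            if line.startswith("#NAMES"):
                names = line.split("\t")[1:]
            elif line.startswith("#REGION"):
                parts = line.split("\t")[1:]
                region = (parts[0], int(parts[1]), int(parts[2]))
            elif line.startswith("#"):
                continue
            else:
                parts = line.split("\t")
                if len(parts) != 2 or names is None or region is None:
                    raise ValueError(f"malformed sites record at line {ln}: {line!r}")
                if len(parts[1]) != len(names):
                    raise ValueError(
                        f"line {ln}: {len(parts[1])} bases for {len(names)} lineages"
                    )
                positions.append(int(parts[0]))
                rows.append(parts[1].upper())
    finally:
        if close:
            fh.close()
    if names is None or region is None:
        raise ValueError("sites input missing #NAMES or #REGION header")
    chrom, start, end = region
    pos0 = np.asarray(positions, dtype=np.int64) - start
    return names, chrom, start, end, pos0, rows


def sites_to_biallelic(rows: list[str]):
    """Encode base strings as 0/1/-1; >2-allele sites are dropped (counted)."""
    keep_alleles, keep_idx = [], []
    dropped = 0
    for k, row in enumerate(rows):
        obs = [c for c in row if c != "N"]
        uniq = sorted(set(obs), key=row.index)
        if len(uniq) > 2:
            dropped += 1
            continue
        a0 = uniq[0] if uniq else "A"
        enc = np.array(
            [-1 if c == "N" else (0 if c == a0 else 1) for c in row], dtype=np.int8
        )
        keep_alleles.append(enc)
        keep_idx.append(k)
    if keep_alleles:
        mat = np.stack(keep_alleles, axis=1)
    else:
        mat = np.zeros((len(rows[0]) if rows else 0, 0), dtype=np.int8)
    return mat, np.asarray(keep_idx, dtype=np.int64), dropped


def load_alignment(
    path,
    fmt: str = "sites",
    compress: int = 10,
    mu=DEFAULT_MU,
    masks=None,
    samples: Sequence[SampleConfig] = (),
    region: Optional[tuple[str, int, int]] = None,
) -> CompressedAlignment:
    """Load a sites or VCF input into a :class:`CompressedAlignment`."""
    if fmt == "sites":
        names, chrom, start, end, pos0, rows = read_sites(path)
        mat, keep, dropped = sites_to_biallelic(rows)
        window = end - start + 1
        return compress_alignment(
            pos0[keep], mat, window, names, compress=compress, mu=mu,
            masks=masks, samples=samples, chrom=chrom, offset=start - 1,
            n_dropped=dropped,
        )
    if fmt == "vcf":
        if region is None:
            raise ValueError("VCF input requires region=(chrom, start, end)")
        return _load_vcf(path, region, compress, mu, masks, samples)
    raise ValueError(f"unknown alignment format {fmt!r}")


def _load_vcf(path, region, compress, mu, masks, samples):
    from cyvcf2 import VCF

    chrom, start, end = region
    vcf = VCF(str(path))
    vcf_samples = list(vcf.samples)
    ploidy = {s.sample_id: s.ploidy for s in samples} if samples else {}
    lineage_names = []
    for s in vcf_samples:
        p = ploidy.get(s, 2)
        lineage_names.extend([s] if p == 1 else [f"{s}_1", f"{s}_2"])
    positions, cols = [], []
    dropped = 0
    # iterate and filter: plain-text VCFs carry no index for region queries
    for v in (x for x in vcf if x.CHROM == chrom and start <= x.POS <= end):
        if len(v.ALT) != 1 or len(v.REF) != 1 or len(v.ALT[0]) != 1:
            dropped += 1
            continue
        row = []
        for si, s in enumerate(vcf_samples):
            g = v.genotypes[si]
            p = ploidy.get(s, 2)
            alleles = g[:p]
            row.extend(-1 if a is None or a < 0 else int(a) for a in alleles)
        positions.append(v.POS - start)
        cols.append(np.asarray(row, dtype=np.int8))
    mat = (np.stack(cols, axis=1) if cols
           else np.zeros((len(lineage_names), 0), dtype=np.int8))
    window = end - start + 1
    return compress_alignment(
        np.asarray(positions), mat, window, lineage_names, compress=compress,
        mu=mu, masks=masks, samples=samples, chrom=chrom, offset=start - 1,
        n_dropped=dropped,
    )


def write_sites(path_or_buf, aln_names, chrom, start, end, positions, rows):
    """Write the sites dialect (inverse of :func:`read_sites`)."""
    close = False
    if isinstance(path_or_buf, (str, bytes)):
        fh = open(path_or_buf, "w")
        close = True
    else:
        fh = path_or_buf
    try:
        fh.write("#NAMES\t" + "\t".join(aln_names) + "\n")
        fh.write(f"#REGION\t{chrom}\t{start}\t{end}\n")
        for p, row in zip(positions, rows):
            fh.write(f"{p}\t{row}\n")
    finally:
        if close:
            fh.close()


def read_bed(path) -> list[tuple[str, int, int]]:
    out = []
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split()
            out.append((parts[0], int(parts[1]), int(parts[2])))
    return out


# ------------------------------------------------------------------ #
# model config
# ------------------------------------------------------------------ #

def load_model(source) -> DemographicModel:
    """Build a model from a YAML/JSON file path, text, or dict."""
    if isinstance(source, dict):
        d = source
    else:
        try:
            with open(source) as fh:
                d = yaml.safe_load(fh)
        except (OSError, TypeError):
            d = yaml.safe_load(source)
    pops = [
        Population(
            name=p["name"],
            parent=p.get("parent"),
            divergence_time=p.get("divergence_time"),
            sizes=(
                [tuple(x) for x in p["sizes"]]
                if isinstance(p.get("sizes"), list) else p.get("sizes")
            ),
            is_ghost=bool(p.get("ghost", False)),
        )
        for p in d["populations"]
    ]
    bands = [
        MigrationBand(b["source"], b["dest"], float(b["time"]),
                      float(b.get("prior_rate", 0.01)))
        for b in d.get("bands", [])
    ]
    samples = [
        SampleConfig(
            sample_id=s["id"], population=s["population"],
            age=float(s.get("age", 0)), ploidy=int(s.get("ploidy", 2)),
            phased=bool(s.get("phased", False)),
        )
        for s in d.get("samples", [])
    ]
    return DemographicModel(
        grid=build_time_grid(d["times"]),
        populations=pops,
        bands=bands,
        samples=samples,
        generation_time=float(d.get("generation_time", 29.0)),
    )


def dump_model(model: DemographicModel) -> str:
    d = {
        "generation_time": model.generation_time,
        "times": list(model.grid.coal_times),
        "populations": [
            {
                "name": p.name,
                **({"parent": p.parent, "divergence_time": p.divergence_time}
                   if p.parent else {}),
                **({"ghost": True} if p.is_ghost else {}),
                **({"sizes": (p.sizes if np.isscalar(p.sizes)
                              else [list(x) for x in p.sizes])}
                   if p.sizes is not None else {}),
            }
            for p in model.populations
        ],
        "bands": [
            {"source": b.source, "dest": b.dest, "time": b.time,
             "prior_rate": b.prior_rate}
            for b in model.bands
        ],
        "samples": [
            {"id": s.sample_id, "population": s.population, "age": s.age,
             "ploidy": s.ploidy, "phased": s.phased}
            for s in model.samples
        ],
    }
    return yaml.safe_dump(d, sort_keys=False)


# ------------------------------------------------------------------ #
# outputs
# ------------------------------------------------------------------ #

def write_calls_bed(calls, path) -> None:
    """Calls as BED: chrom, start, end, band, score (1000 * mean posterior),
    strand, zygosity."""
    with open(path, "w") as fh:
        fh.write("#chrom\tstart\tend\tband\tscore\tstrand\tzygosity\tindividual\n")
        for c in calls:
            fh.write(
                f"{c.chrom}\t{c.start}\t{c.end}\t{c.band}\t"
                f"{int(round(1000 * c.mean_posterior))}\t.\t{c.zygosity}\t"
                f"{c.individual}\n"
            )


def read_calls_bed(path):
    from .calling import RegionCall

    out = []
    with open(path) as fh:
        for line in fh:
            if line.startswith("#") or not line.strip():
                continue
            f = line.rstrip("\n").split("\t")
            out.append(RegionCall(
                chrom=f[0], start=int(f[1]), end=int(f[2]), band=f[3],
                individual=f[7], zygosity=f[6],
                mean_posterior=int(f[4]) / 1000.0,
            ))
    return out


def write_bedgraph(track, path, which: str = "any") -> None:
    """Posterior track as bedGraph; adjacent equal-valued columns merged."""
    p = {"any": track.p_any, "het": track.p_het, "hom": track.p_hom}[which]
    with open(path, "w") as fh:
        fh.write(
            f'track type=bedGraph name="{track.band}_{track.individual}_{which}"\n'
        )
        i = 0
        while i < len(p):
            j = i
            while j + 1 < len(p) and p[j + 1] == p[i]:
                j += 1
            fh.write(
                f"{track.chrom}\t{track.bp_starts[i]}\t{track.bp_ends[j]}\t"
                f"{p[i]:.6g}\n"
            )
            i = j + 1


def write_stats(records, path) -> None:
    """Per-iteration chain statistics as TSV."""
    rows = []
    for r in records:
        row = {"iteration": r.iteration, "loglik": r.loglik,
               "retained": int(r.sample is not None)}
        for k, v in r.migrant_columns.items():
            row[f"migrant_cols[{k}]"] = v
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def write_arg_sample(arg, model, fh, iteration: int) -> None:
    """Line-based ARG serialization: one block per local tree.

    ``TREE start end`` is followed by one ``node parent time path`` row per
    node (slot ids; -1 root, -2 absent).
    """
    fh.write(f"SAMPLE\t{iteration}\t{arg.L}\n")
    for start, end, tree in arg.segments():
        fh.write(f"TREE\t{start}\t{end}\n")
        for v in range(tree.n_nodes):
            fh.write(
                f"{v}\t{int(tree.parent[v])}\t{int(tree.time[v])}\t"
                f"{int(tree.path[v])}\n"
            )
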