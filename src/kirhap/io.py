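"""Tabular and FASTA round-tripping for the pipeline's file formats.

Every output file starts with ``#``-prefixed metadata lines (tool version,
seed, parameters) so a result can always be traced to the run that
produced it.
"""

from __future__ import annotations

import json
from pathlib import Path

from Bio import SeqIO

from . import __version__
from .assays import GenotypeCall, PeakObservation
from .errors import ParseError
from .loci import CANONICAL_LOCI
from .reference import CopyVector
from .simulate import AlignedTriplet


def _metadata_lines(meta: dict | None) -> list[str]:
    meta = {"tool": f"kirhap {__version__}", **(meta or {})}
    return [f"# {k}={v}" for k, v in meta.items()]


def _write(path, header_cols, rows, meta=None):
    lines = _metadata_lines(meta)
    lines.append("\t".join(header_cols))
    lines += ["\t".join(str(x) for x in row) for row in rows]
    Path(path).write_text("\n".join(lines) + "\n")


def _data_lines(path):
    for ln in Path(path).read_text().splitlines():
        if ln and not ln.startswith("#"):
            yield ln


# --------------------------------------------------------------------------
# Peak observations
# --------------------------------------------------------------------------

def write_peaks(path, observations, meta=None) -> None:
    rows = []
    for ob in observations:
        for base, h in ob.heights:
            rows.append((ob.sample_id, ob.assay_name, ob.position, base,
                         f"{h:.4f}"))
    _write(path, ["sample_id", "assay", "position", "base", "height"],
           rows, meta)


def read_peaks(path) -> dict[str, list[PeakObservation]]:
    """Peaks grouped by sample (insertion order preserved)."""
    acc: dict[tuple, dict] = {}
    order: dict[str, None] = {}
    lines = list(_data_lines(path))
    if not lines:
        raise ParseError(f"{path}: empty peak table")
    header = lines[0].split("\t")
    if header[:5] != ["sample_id", "assay", "position", "base", "height"]:
        raise ParseError(f"{path}: unexpected peak table header {header}")
    for ln in lines[1:]:
        try:
            sid, assay, pos, base, height = ln.split("\t")
            key = (sid, assay, int(pos))
            acc.setdefault(key, {})[base] = float(height)
        except ValueError as exc:
            raise ParseError(f"{path}: bad peak row {ln!r}") from exc
        order.setdefault(sid)
    out: dict[str, list[PeakObservation]] = {s: [] for s in order}
    for (sid, assay, pos), heights in acc.items():
        out[sid].append(PeakObservation.make(sid, assay, pos, heights))
    return out


# --------------------------------------------------------------------------
# Genotype calls
# --------------------------------------------------------------------------

_GENO_LOCI = list(CANONICAL_LOCI) + ["2DL1/S1", "2DP1/L1", "3DL1/L2", "2DS2/S3"]


def write_genotypes_tsv(path, calls, meta=None) -> None:
    rows = []
    for c in calls:
        d = c.copies.as_dict()
        rows.append([c.sample_id] + [d.get(l, 0) for l in _GENO_LOCI]
                    + [";".join(c.quality) or "."])
    _write(path, ["sample_id"] + _GENO_LOCI + ["quality"], rows, meta)


def write_genotypes_json(path, calls, meta=None) -> None:
    payload = {
        "metadata": {"tool": f"kirhap {__version__}", **(meta or {})},
        "calls": [
            {
                "sample_id": c.sample_id,
                "copies": c.copies.as_dict(),
                "alternatives": [v.as_dict() for v in c.alternatives],
                "presence_evidence": c.presence_evidence,
                "discordances": [list(d) for d in c.discordances],
                "provisional_loci": c.provisional_loci,
                "quality": c.quality,
            }
            for c in calls
        ],
    }
    Path(path).write_text(json.dumps(payload, indent=2) + "\n")


def read_genotypes_tsv(path) -> list[GenotypeCall]:
    lines = list(_data_lines(path))
    header = lines[0].split("\t")
    if header[0] != "sample_id":
        raise ParseError(f"{path}: unexpected genotype header")
    loci = header[1:-1]
    calls = []
    for ln in lines[1:]:
        f = ln.split("\t")
        counts = {l: int(v) for l, v in zip(loci, f[1:-1]) if int(v)}
        calls.append(GenotypeCall(
            sample_id=f[0],
            copies=CopyVector.from_dict(counts, "diploid",
                                        collapse_2DS35=False),
            quality=[] if f[-1] == "." else f[-1].split(";"),
        ))
    return calls


# --------------------------------------------------------------------------
# Resolutions, frequencies, LD, scans
# --------------------------------------------------------------------------

def write_resolutions_jsonl(path, resolutions, meta=None) -> None:
    lines = _metadata_lines(meta)
    for r in resolutions:
        lines.append(json.dumps({
            "sample_id": r.sample_id,
            "status": r.status,
            "pairs": [list(p) for p in r.consistent_pairs],
            "chosen_pair": list(r.chosen_pair) if r.chosen_pair else None,
            "rule_trace": [list(t) for t in r.rule_trace],
        }))
    Path(path).write_text("\n".join(lines) + "\n")


def write_resolutions_tsv(path, resolutions, meta=None) -> None:
    rows = []
    for r in resolutions:
        h1, h2 = (r.chosen_pair if r.chosen_pair
                  else (r.consistent_pairs[0] if r.consistent_pairs
                        else (".", ".")))
        rows.append((r.sample_id, h1, h2, r.status, len(r.consistent_pairs)))
    _write(path, ["sample_id", "hap1", "hap2", "status", "n_pairs"],
           rows, meta)


def write_frequencies(path, estimate, meta=None) -> None:
    meta = dict(meta or {})
    meta.update(n_chromosomes=estimate.n_chromosomes,
                converged=estimate.converged,
                n_excluded=estimate.n_excluded,
                loglik=f"{estimate.loglik_trace[-1]:.6f}")
    rows = [
        (name, f"{f:.8f}", round(f * estimate.n_chromosomes))
        for name, f in sorted(estimate.frequencies.items(),
                              key=lambda kv: -kv[1])
    ]
    _write(path, ["haplotype", "frequency", "chromosomes"], rows, meta)


def write_frequencies_json(path, estimate, meta=None) -> None:
    Path(path).write_text(json.dumps({
        "metadata": {"tool": f"kirhap {__version__}", **(meta or {})},
        "frequencies": estimate.frequencies,
        "loglik_trace": estimate.loglik_trace,
        "n_chromosomes": estimate.n_chromosomes,
        "n_excluded": estimate.n_excluded,
        "converged": estimate.converged,
    }, indent=2) + "\n")


def write_motif_summary(path, summary, meta=None) -> None:
    rows = [(sect, name, f"{100 * f:.2f}")
            for sect, name, f in summary.as_rows()]
    _write(path, ["section", "pattern", "percent"], rows, meta)


def write_ld(path, ld, meta=None) -> None:
    """Both matrices stacked long-form: gene_a, gene_b, dprime, rsq."""
    rows = []
    n = len(ld.genes)
    for i in range(n):
        for j in range(i + 1, n):
            if ld.undefined[i] or ld.undefined[j]:
                dp = r2 = "NA"
            else:
                dp, r2 = f"{ld.dprime[i, j]:.6f}", f"{ld.rsq[i, j]:.6f}"
            rows.append((ld.genes[i], ld.genes[j], dp, r2))
    meta = dict(meta or {})
    meta.setdefault("multiple_testing_correction", "none (raw LD map)")
    _write(path, ["gene_a", "gene_b", "dprime", "rsq"], rows, meta)


def write_scan_calls(path, calls, meta=None) -> None:
    rows = [
        (c.interval[0], c.interval[1], f"{c.statistic:.4f}",
         f"{c.p_adjusted:.3e}",
         f"{c.left_support[0]}/{c.left_support[1]}",
         f"{c.right_support[0]}/{c.right_support[1]}")
        for c in calls
    ]
    _write(path, ["start", "end", "chi2", "p_adjusted", "left_A/B",
                  "right_A/B"], rows, meta)


def write_identity_profile(path, rows, names, meta=None) -> None:
    _write(path, ["window_start"] + [f"identity_{n}" for n in names],
           [(r[0],) + tuple(f"{x:.3f}" for x in r[1:]) for r in rows], meta)


# --------------------------------------------------------------------------
# FASTA triplets
# --------------------------------------------------------------------------

def write_triplet_fasta(path, triplet: AlignedTriplet) -> None:
    with open(path, "w") as fh:
        for name, seq in zip(triplet.names,
                             (triplet.query, triplet.parent_a,
                              triplet.parent_b)):
            fh.write(f">{name}\n")
            for i in range(0, len(seq), 70):
                fh.write(seq[i:i + 70] + "\n")


def read_triplet_fasta(path, query_name=None) -> AlignedTriplet:
    """Read an aligned FASTA; the first record is the query unless
    ``query_name`` selects another."""
    records = list(SeqIO.parse(str(path), "fasta"))
    if len(records) < 3:
        raise ParseError(f"{path}: need at least 3 aligned records")
    if query_name is not None:
        qi = next((i for i, r in enumerate(records) if r.id == query_name),
                  None)
        if qi is None:
            raise ParseError(f"{path}: no record named {query_name!r}")
        records.insert(0, records.pop(qi))
    q, a, b = records[0], records[1], records[2]
    return AlignedTriplet(
        query=str(q.seq).upper(),
        parent_a=str(a.seq).upper(),
        parent_b=str(b.seq).upper(),
        names=(q.id, a.id, b.id),
    )


def write_cohort(path, cohort, meta=None) -> None:
    _write(path, ["sample_id", "hap1", "hap2"], cohort, meta)


def read_cohort(path):
    lines = list(_data_lines(path))
    if lines[0].split("\t") != ["sample_id", "hap1", "hap2"]:
        raise ParseError(f"{path}: unexpected cohort header")
    return [tuple(ln.split("\t")) for ln in lines[1:]]
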