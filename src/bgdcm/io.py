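"""Plain-text readers and writers for every pipeline artifact.

All formats are structured text with an embedded version so artifacts are
inspectable and diffable; floats are written with 17 significant digits so
write-then-read round-trips are exact.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import yaml

from .ar import TimeSeriesRecord
from .inversion import Posterior
from .spectra import CrossSpectra

FORMAT_VERSION = "1"


def _fmt(x: float) -> str:
    return format(float(x), ".17g")


class FormatVersionError(ValueError):
    pass


def _check_version(found: str, kind: str) -> None:
    if str(found) != FORMAT_VERSION:
        raise FormatVersionError(
            f"{kind} file version {found!r} != supported {FORMAT_VERSION!r}"
        )


# ---------------------------------------------------------------------------
# CrossSpectra: header lines then one row per (i, j, f) with re/im parts
# ---------------------------------------------------------------------------

def write_csd(cs: CrossSpectra, path: str | Path) -> None:
    path = Path(path)
    with path.open("w") as fh:
        fh.write(f"# bgdcm-csd v{FORMAT_VERSION}\n")
        fh.write("# channels: " + " ".join(cs.channels) + "\n")
        fh.write("# sampling_rate: " + _fmt(cs.sampling_rate) + "\n")
        fh.write("# grid: " + " ".join(_fmt(f) for f in cs.grid) + "\n")
        fh.write("# columns: i j freq re im\n")
        for i in range(cs.n_channels):
            for j in range(cs.n_channels):
                for fi, f in enumerate(cs.grid):
                    v = cs.values[i, j, fi]
                    fh.write(f"{i} {j} {_fmt(f)} {_fmt(v.real)} {_fmt(v.imag)}\n")


def read_csd(path: str | Path) -> CrossSpectra:
    path = Path(path)
    channels: list[str] = []
    grid: np.ndarray | None = None
    fs = 250.0
    rows = []
    with path.open() as fh:
        first = fh.readline().strip()
        if not first.startswith("# bgdcm-csd v"):
            raise ValueError(f"{path} is not a bgdcm CSD file")
        _check_version(first.split("v")[-1], "CSD")
        for line in fh:
            line = line.strip()
            if line.startswith("# channels:"):
                channels = line.split(":", 1)[1].split()
            elif line.startswith("# sampling_rate:"):
                fs = float(line.split(":", 1)[1])
            elif line.startswith("# grid:"):
                grid = np.array([float(x) for x in line.split(":", 1)[1].split()])
            elif line.startswith("#") or not line:
                continue
            else:
                i, j, f, re, im = line.split()
                rows.append((int(i), int(j), float(re), float(im)))
    if grid is None or not channels:
        raise ValueError(f"{path}: missing header fields")
    C, F = len(channels), len(grid)
    values = np.zeros((C, C, F), dtype=complex)
    if len(rows) != C * C * F:
        raise ValueError(f"{path}: expected {C*C*F} rows, found {len(rows)}")
    k = 0
    for i in range(C):
        for j in range(C):
            for fi in range(F):
                ri, rj, re, im = rows[k]
                if (ri, rj) != (i, j):
                    raise ValueError(f"{path}: row ordering corrupt at entry {k}")
                values[i, j, fi] = re + 1j * im
                k += 1
    return CrossSpectra(grid, values, channels, fs)


# ---------------------------------------------------------------------------
# TimeSeriesRecord: labels line, sampling-rate line, delimited matrix
# ---------------------------------------------------------------------------

def write_timeseries(rec: TimeSeriesRecord, path: str | Path) -> None:
    path = Path(path)
    with path.open("w") as fh:
        fh.write("\t".join(rec.channels) + "\n")
        fh.write(_fmt(rec.sampling_rate) + "\n")
        for row in rec.samples:
            fh.write("\t".join(_fmt(x) for x in row) + "\n")


def read_timeseries(path: str | Path) -> TimeSeriesRecord:
    path = Path(path)
    with path.open() as fh:
        channels = fh.readline().strip().split("\t")
        fs = float(fh.readline().strip())
        samples = np.loadtxt(fh)
    if samples.ndim == 1:
        samples = samples[:, None]
    return TimeSeriesRecord(samples=samples, sampling_rate=fs, channels=channels)


# ---------------------------------------------------------------------------
# Posterior: JSON document
# ---------------------------------------------------------------------------

def write_posterior(post: Posterior, path: str | Path) -> None:
    doc = {
        "format": "bgdcm-posterior",
        "version": FORMAT_VERSION,
        "names": list(post.names),
        "mean": [float(x) for x in post.mean],
        "cov": [[float(x) for x in row] for row in post.cov],
        "lambda": float(post.lam),
        "lambda_var": float(post.lam_var),
        "free_energy": float(post.free_energy),
        "trace": [float(x) for x in post.trace],
        "data_hash": post.data_hash,
        "converged": bool(post.converged),
        "n_iter": int(post.n_iter),
    }
    Path(path).write_text(json.dumps(doc, indent=1))


def read_posterior(path: str | Path) -> Posterior:
    doc = json.loads(Path(path).read_text())
    if doc.get("format") != "bgdcm-posterior":
        raise ValueError(f"{path} is not a bgdcm posterior file")
    _check_version(doc.get("version"), "posterior")
    return Posterior(
        names=list(doc["names"]),
        mean=np.array(doc["mean"], dtype=float),
        cov=np.array(doc["cov"], dtype=float),
        lam=float(doc["lambda"]),
        lam_var=float(doc["lambda_var"]),
        free_energy=float(doc["free_energy"]),
        trace=[float(x) for x in doc["trace"]],
        data_hash=doc.get("data_hash", ""),
        converged=bool(doc.get("converged", True)),
        n_iter=int(doc.get("n_iter", 0)),
    )


# ---------------------------------------------------------------------------
# Cohort directory: manifest + per-subject files
# ---------------------------------------------------------------------------

def write_cohort(bundle, outdir: str | Path) -> None:
    from .cohort import CohortBundle  # noqa: F401  (type only)

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest = dict(bundle.manifest)
    entries = []
    for s, entry in zip(bundle.subjects, manifest["subjects"]):
        entry = dict(entry)
        if s.csd is not None:
            fname = f"{s.subject_id}.csd.txt"
            write_csd(s.csd, outdir / fname)
            entry["csd_file"] = fname
        if s.record is not None:
            fname = f"{s.subject_id}.lfp.tsv"
            write_timeseries(s.record, outdir / fname)
            entry["timeseries_file"] = fname
        entries.append(entry)
    manifest["subjects"] = entries
    with (outdir / "manifest.yaml").open("w") as fh:
        yaml.safe_dump(manifest, fh, sort_keys=False)


def read_manifest(outdir: str | Path) -> dict:
    with (Path(outdir) / "manifest.yaml").open() as fh:
        return yaml.safe_load(fh)


def load_cohort(outdir: str | Path):
    """Reload the written artifacts of a cohort directory (data files only;
    ground-truth parameters are regenerated from the manifest seeds via
    :func:`bgdcm.cohort.make_cohort`)."""
    from .ar import TimeSeriesRecord  # noqa: F401
    outdir = Path(outdir)
    manifest = read_manifest(outdir)
    out = []
    for entry in manifest["subjects"]:
        item = {"id": entry["id"], "regime": entry["regime"], "seed": entry["seed"]}
        if "csd_file" in entry:
            item["csd"] = read_csd(outdir / entry["csd_file"])
        if "timeseries_file" in entry:
            item["record"] = read_timeseries(outdir / entry["timeseries_file"])
        out.append(item)
    return manifest, out
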