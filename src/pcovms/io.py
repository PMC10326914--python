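"""Readers and writers: the plain-text microscan dialect, FASTA input,
YAML configuration, and TSV report output.

Scan dialect, one block per microscan::

    # comment
    SCAN 0
    512.2827<TAB>3.0
    530.3045<TAB>2.5

    SCAN 1
    ...

m/z must ascend within a scan; blocks are separated by blank lines (the
``SCAN`` header alone also delimits).  Reading bins every line onto the
requested uniform grid, so simulated and instrument-exported text pass
through the same path.
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Mapping, Sequence, TextIO

import numpy as np
import yaml
from Bio import SeqIO

from .chem import ACETYL, Modification
from .combinatorics import IsomerSet, enumerate_isomers
from .pcov import GridSpec, IsomerEvidence, PeakCandidate, ScanEnsemble
from .simulate import MixtureModel, make_isomer_mixture_model

logger = logging.getLogger("pcovms")


class ScanFormatError(ValueError):
    """Malformed scan text; message carries the offending line/scan."""


def write_scans(ensemble: ScanEnsemble, path: str | Path, skip_zero: bool = True) -> None:
    """Write an ensemble in the text scan dialect (zero bins omitted)."""
    with open(path, "w") as fh:
        fh.write("# pcovms scan export\n")
        fh.write(f"# n_scans={ensemble.n_scans} n_bins={ensemble.n_bins}\n")
        for i in range(ensemble.n_scans):
            fh.write(f"SCAN {i}\n")
            row = ensemble.intensities[i]
            idx = np.nonzero(row)[0] if skip_zero else np.arange(row.size)
            for j in idx:
                fh.write(f"{ensemble.mz_grid[j]:.4f}\t{row[j]:.10g}\n")
            fh.write("\n")


def _iter_scan_blocks(fh: TextIO):
    current: list[tuple[float, float]] | None = None
    scan_no = None
    for lineno, line in enumerate(fh, start=1):
        line = line.strip()
        if not line:
            continue
        if line.startswith("#"):
            continue
        if line.upper().startswith("SCAN"):
            if current is not None:
                yield scan_no, current
            parts = line.split()
            scan_no = parts[1] if len(parts) > 1 else str(lineno)
            current = []
            continue
        if current is None:
            raise ScanFormatError(f"line {lineno}: data before any SCAN header")
        parts = line.split("\t") if "\t" in line else line.split()
        try:
            mz, inten = float(parts[0]), float(parts[1])
        except (IndexError, ValueError) as exc:
            raise ScanFormatError(f"line {lineno}: cannot parse {line!r}") from exc
        if inten < 0:
            raise ScanFormatError(f"line {lineno}: negative intensity")
        if current and mz <= current[-1][0]:
            raise ScanFormatError(
                f"scan {scan_no}: m/z not strictly increasing at line {lineno}"
            )
        current.append((mz, inten))
    if current is not None:
        yield scan_no, current


def read_scans(path: str | Path, grid: GridSpec) -> ScanEnsemble:
    """Parse the scan dialect and bin every scan onto ``grid``."""
    rows = []
    with open(path) as fh:
        for scan_no, peaks in _iter_scan_blocks(fh):
            row = np.zeros(grid.n_bins)
            if peaks:
                mz = np.array([p[0] for p in peaks])
                inten = np.array([p[1] for p in peaks])
                idx = grid.index_of(mz)
                ok = (idx >= 0) & (idx < grid.n_bins)
                np.add.at(row, idx[ok], inten[ok])
            rows.append(row)
    if not rows:
        raise ScanFormatError(f"{path}: no scans found")
    ens = ScanEnsemble(
        mz_grid=grid.centers(),
        intensities=np.stack(rows),
        metadata={"source": str(path), "grid": (grid.lo, grid.hi, grid.step)},
    )
    logger.info("read %d scans x %d bins from %s", ens.n_scans, ens.n_bins, path)
    return ens


def read_fasta(path: str | Path) -> dict[str, str]:
    """FASTA records as {id: uppercase sequence}; empty file -> empty dict."""
    return {
        rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")
    }


# --- configuration ----------------------------------------------------------


def load_config(path: str | Path) -> dict:
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    return cfg or {}


def modification_from_config(cfg: Mapping | str | None) -> Modification:
    """Build a Modification from config; the default is lysine acetylation."""
    if cfg is None or cfg == "acetyl":
        return ACETYL
    if isinstance(cfg, str):
        raise ValueError(f"unknown built-in modification {cfg!r}")
    return Modification(
        name=str(cfg["name"]),
        delta_mass=float(cfg["delta_mass"]),
        target_residues=frozenset(cfg["target_residues"]),
        blocks_cleavage=bool(cfg.get("blocks_cleavage", False)),
    )


def grid_from_config(cfg: Mapping) -> GridSpec:
    return GridSpec(
        lo=float(cfg["lo"]), hi=float(cfg["hi"]), step=float(cfg.get("step", 0.2))
    )


def isomer_set_from_config(cfg: Mapping) -> tuple[IsomerSet, list[str]]:
    """An isomer set from a config mapping with ``peptide``, per-component
    ``sites`` lists, optional ``modification`` and ``parent_offset``."""
    mod = modification_from_config(cfg.get("modification"))
    peptide = cfg["peptide"]
    offset = int(cfg.get("parent_offset", 1))
    comps = cfg["components"]
    sites_lists = [tuple(int(s) for s in c["sites"]) for c in comps]
    m = len(sites_lists[0])
    if any(len(s) != m for s in sites_lists):
        raise ValueError("all components must place the same number of mods")
    from .chem import ModifiedPeptide

    isomers = [
        ModifiedPeptide.from_sites(peptide, mod, sites, offset)
        for sites in sites_lists
    ]
    iso_set = IsomerSet(
        peptide=peptide,
        modification=mod,
        multiplicity=m,
        isomers=isomers,
        parent_offset=offset,
    )
    names = [
        c.get("name", iso.label) for c, iso in zip(comps, iso_set.isomers)
    ]
    return iso_set, names


def model_from_config(cfg: Mapping) -> tuple[MixtureModel, list[str]]:
    """A simulation model from config: isomer set + abundances + grid and
    optional generator parameters."""
    iso_set, names = isomer_set_from_config(cfg)
    abundances = [float(c.get("abundance", 1.0)) for c in cfg["components"]]
    kwargs = {}
    for key in ("tic_fluctuation", "noise_sd", "peak_width", "total_precursors"):
        if key in cfg:
            kwargs[key] = float(cfg[key])
    grid = grid_from_config(cfg["grid"]) if "grid" in cfg else None
    model = make_isomer_mixture_model(
        iso_set, abundances, grid=grid, names=names, **kwargs
    )
    return model, names


# --- TSV report output ------------------------------------------------------


def peaks_to_tsv(peaks: Sequence[PeakCandidate], path: str | Path) -> None:
    """Peak list: 4-decimal m/z plus 1-decimal instrument-style columns."""
    with open(path, "w") as fh:
        fh.write(
            "mz_x\tmz_y\tmz_x_1dp\tmz_y_1dp\tapex_height\tvolume\tscore\n"
        )
        for p in peaks:
            score = "" if p.score is None else f"{p.score:.4f}"
            fh.write(
                f"{p.apex_mz[0]:.4f}\t{p.apex_mz[1]:.4f}\t"
                f"{p.apex_mz[0]:.1f}\t{p.apex_mz[1]:.1f}\t"
                f"{p.apex_height:.6g}\t{p.volume:.6g}\t{score}\n"
            )


def evidence_to_tsv(evidence: IsomerEvidence, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write(
            "isomer\tn_matched\tbest_score\tbest_volume\tdetected\t"
            "relative_abundance\n"
        )
        for iso in evidence.isomers:
            frac = evidence.relative_abundance.get(iso)
            frac_s = "" if frac is None else f"{frac:.4f}"
            fh.write(
                f"{iso}\t{len(evidence.matches[iso])}\t"
                f"{evidence.best_score(iso):.4f}\t"
                f"{evidence.best_volume(iso):.6g}\t"
                f"{int(evidence.detected(iso))}\t{frac_s}\n"
            )
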