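"""End-to-end runs emitting the report tables, as plain library functions.

Three entry points mirror the three things a user does:

* :func:`run_consensus` — score response elements against the consensus
  motif and write mismatch reports;
* :func:`run_simulate` — generate a synthetic ensemble bundle (multi-model
  PDB + mapping TOML + truth JSON);
* :func:`run_fingerprint` — run every analysis stage on an ensemble and
  write the table-shaped TSV/JSON reports plus a machine-readable manifest.

All outputs are deterministic given identical inputs and seed: TSV floats
are written with a fixed format and JSON keys are sorted, so two identical
runs produce byte-identical files.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Optional, Union

import numpy as np
import pandas as pd

from . import synthetic_ensembles as synth
from .dna_geometry import base_pair_frames, bend_angle, duplex_pairs
from .dynamics_stats import covariance_map
from .ensemble_io import (
    Ensemble,
    FrameWindow,
    SelectionSpec,
    read_multimodel_pdb,
)
from .geom_descriptors import org_geometry, rmsd_series, rmsf
from .interface_contacts import (
    DEFAULT_CUTOFF,
    arg248_distances,
    arg280_contact,
    lys120_fingerprint,
    occupancy,
    saltbridge_network,
)
from .mapping import MappingConfig
from .re_model import (
    KNOWN_RESPONSE_ELEMENTS,
    MismatchReport,
    parse_re,
    parse_re_fasta,
    score_consensus,
)

_FLOAT_FMT = "%.6f"


def _write_tsv(df: pd.DataFrame, path: Path, index: bool = False) -> None:
    df.to_csv(path, sep="\t", index=index, float_format=_FLOAT_FMT)


def run_consensus(
    elements: Union[None, Mapping[str, str], str, Path] = None,
    out_dir: Union[str, Path, None] = None,
) -> Mapping[str, MismatchReport]:
    """Score response elements against the consensus motif.

    ``elements`` is a mapping of name -> 20-base sequence, a FASTA path, or
    ``None`` for the six built-in naturally occurring elements.  When
    ``out_dir`` is given, one TSV + JSON report per element and a summary
    TSV are written.
    """
    if elements is None:
        elements = {
            name: info["sequence"] for name, info in KNOWN_RESPONSE_ELEMENTS.items()
        }
    elif isinstance(elements, (str, Path)):
        re_obj = parse_re_fasta(elements)
        elements = {re_obj.name: re_obj.sequence}
    reports = {}
    for name, sequence in elements.items():
        reports[name] = score_consensus(parse_re(name, sequence))
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        summary = []
        for name, report in reports.items():
            stem = "".join(ch if ch.isalnum() else "_" for ch in name)
            report.to_tsv(out_dir / f"consensus_{stem}.tsv")
            report.to_json(out_dir / f"consensus_{stem}.json")
            summary.append({"name": name, "mismatch_count": report.mismatch_count})
        _write_tsv(pd.DataFrame(summary), out_dir / "consensus_summary.tsv")
    return reports


def run_simulate(
    out_dir: Union[str, Path],
    half_site: str = "AGGCATGTGC",  # 14-3-3σ first half site
    name: str = "14-3-3sigma-h1",
    truth: Optional[synth.PlantedTruth] = None,
    n_frames: Optional[int] = None,
    seed: int = 0,
) -> Mapping[str, Path]:
    """Generate and write a synthetic ensemble bundle.

    Returns the paths of the written ensemble/mapping/truth files.
    """
    template = synth.build_template(half_site, name=name)
    if truth is None:
        truth = synth.default_truth(n_frames or 2000)
    elif n_frames is not None and truth.n_frames != n_frames:
        raise ValueError("pass n_frames either in truth or as argument, not both")
    ens, record = synth.generate(template, truth, seed=seed)
    return synth.write_bundle(out_dir, ens, template, record)


@dataclass
class RunConfig:
    """Inputs and parameters of one fingerprint run."""

    ensemble_path: Union[str, Path]
    mapping_path: Union[str, Path]
    re_name: str
    re_sequence: str  # 20 bases, or a 10-base half site
    out_dir: Union[str, Path]
    cutoff: float = DEFAULT_CUTOFF
    occupancy_window: float = 2 / 3  # tail fraction ("last 20 ns" of 30 ns)
    fluctuation_window: float = 1 / 6  # tail fraction ("final 5 ns")
    seed: int = 0

    def __post_init__(self):
        if not 0 < self.occupancy_window <= 1 or not 0 < self.fluctuation_window <= 1:
            raise ValueError("window fractions must lie in (0, 1]")
        if self.cutoff <= 0:
            raise ValueError("cutoff must be positive")

    @classmethod
    def from_bundle(cls, bundle_dir, out_dir) -> "RunConfig":
        """Configuration for a bundle written by :func:`run_simulate`."""
        bundle_dir = Path(bundle_dir)
        truth = json.loads((bundle_dir / "truth.json").read_text())
        return cls(
            ensemble_path=bundle_dir / "ensemble.pdb",
            mapping_path=bundle_dir / "mapping.toml",
            re_name=truth.get("re_name", "synthetic"),
            re_sequence=truth["re_sequence"],
            out_dir=out_dir,
        )


def run_fingerprint(config: RunConfig) -> Mapping[str, object]:
    """Run every analysis stage and write the report bundle.

    Writes occupancy tables (Lys120 fingerprint, Arg280, salt bridges,
    Arg248), the organizational-geometry table, RMSD/RMSF profiles, bend
    results, per-chain covariance matrices, and a manifest with input
    parameters and output checksums.  Returns the in-memory results.
    """
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    ens = read_multimodel_pdb(config.ensemble_path)
    mapping = MappingConfig.from_toml(config.mapping_path)
    seq = config.re_sequence.upper()
    if len(seq) == 10:
        seq = seq + seq
    re_obj = parse_re(config.re_name, seq)
    occ_window = FrameWindow.tail(config.occupancy_window)
    fluct_window = FrameWindow.tail(config.fluctuation_window)
    quarters = sorted(mapping.quarters)
    results: dict = {}
    written = []

    # --- occupancies -------------------------------------------------------
    lys = lys120_fingerprint(ens, re_obj, mapping, occ_window, config.cutoff)
    results["lys120"] = lys
    _write_tsv(lys.to_dataframe(), out_dir / "lys120_occupancy.tsv")
    written.append("lys120_occupancy.tsv")

    arg280_rows = []
    results["arg280"] = {}
    for quarter in quarters:
        table, series = arg280_contact(
            ens, re_obj, mapping, quarter, occ_window, config.cutoff
        )
        results["arg280"][quarter] = table
        arg280_rows.append(table.to_dataframe())
    _write_tsv(pd.concat(arg280_rows, ignore_index=True), out_dir / "arg280_occupancy.tsv")
    written.append("arg280_occupancy.tsv")

    bridges = saltbridge_network(ens, mapping, occ_window, config.cutoff)
    results["saltbridges"] = bridges
    _write_tsv(
        pd.DataFrame(
            [
                {"quarter": q, "A": b.a, "B": b.b, "C": b.c, "D": b.d}
                for q, b in sorted(bridges.items())
            ]
        ),
        out_dir / "saltbridges.tsv",
    )
    written.append("saltbridges.tsv")

    arg248_rows = []
    results["arg248"] = {}
    for quarter in quarters:
        pair = arg248_distances(ens, mapping, quarter, occ_window, config.cutoff)
        results["arg248"][quarter] = pair
        for series in pair:
            arg248_rows.append(
                {
                    "label": series.label,
                    "occupancy": occupancy(series, config.cutoff),
                    "mean_distance": float(series.values.mean()),
                }
            )
    _write_tsv(pd.DataFrame(arg248_rows), out_dir / "arg248_occupancy.tsv")
    written.append("arg248_occupancy.tsv")

    # --- organizational geometry ------------------------------------------
    org_rows = []
    results["org_geometry"] = {}
    for quarter in quarters:
        geom = org_geometry(ens, mapping, quarter, fluct_window)
        results["org_geometry"][quarter] = geom
        org_rows.append(
            {
                "quarter": quarter,
                "angle_avg_structure": geom.avg_structure_angle,
                "dihedral_avg_structure": geom.avg_structure_dihedral,
                "angle_frame_mean": geom.mean_angle,
                "dihedral_frame_mean": geom.mean_dihedral,
            }
        )
    _write_tsv(pd.DataFrame(org_rows), out_dir / "org_geometry.tsv")
    written.append("org_geometry.tsv")

    # --- DNA bend ----------------------------------------------------------
    from .geom_descriptors import average_structure

    avg = average_structure(ens, fluct_window)
    avg_ens = Ensemble(topology=ens.topology, coords=avg[None])
    bend_rows = []
    segments = {"full": range(1, mapping.n_bp + 1)}
    first_col = mapping.re_offset
    segments["re_half_site"] = range(first_col, first_col + 10)
    for label, columns in segments.items():
        pairs = duplex_pairs(mapping.ref_chain, mapping.comp_chain, mapping.n_bp, columns)
        frames = base_pair_frames(avg_ens, pairs)
        result = bend_angle(frames)
        bend_rows.append(
            {
                "segment": label,
                "n_bp": len(pairs),
                "bend_deg": result.angle_deg,
                "degenerate": result.degenerate,
            }
        )
    results["bend"] = bend_rows
    _write_tsv(pd.DataFrame(bend_rows), out_dir / "bend.tsv")
    written.append("bend.tsv")

    # --- fluctuation analyses (need more than a few frames) ----------------
    if ens.n_frames >= 4:
        rmsd_rows = []
        results["rmsd"] = {}
        for quarter in quarters:
            chain = mapping.protein_chain(quarter)
            fit = SelectionSpec(chain_id=chain, atom_name="CA")
            for key in ("lys120", "arg280", "arg248"):
                resid = mapping.residues[key]
                measure = SelectionSpec(chain_id=chain, res_id=resid)
                series = rmsd_series(ens, fit, measure, reference=0)
                results["rmsd"][(quarter, key)] = series
                rmsd_rows.append(
                    {
                        "quarter": quarter,
                        "residue": key,
                        "mean_rmsd": float(series.mean()),
                        "max_rmsd": float(series.max()),
                    }
                )
        _write_tsv(pd.DataFrame(rmsd_rows), out_dir / "rmsd_profiles.tsv")
        written.append("rmsd_profiles.tsv")

        rmsf_rows = []
        results["rmsf"] = {}
        for quarter in quarters:
            chain = mapping.protein_chain(quarter)
            sel = SelectionSpec(chain_id=chain, atom_name="CA")
            profile = rmsf(ens, sel, fluct_window, fit_sel=sel)
            results["rmsf"][quarter] = profile
            df = profile.to_dataframe()
            df.insert(0, "quarter", quarter)
            rmsf_rows.append(df)
        _write_tsv(pd.concat(rmsf_rows, ignore_index=True), out_dir / "rmsf.tsv")
        written.append("rmsf.tsv")

        results["covariance"] = {}
        for quarter in quarters:
            chain = mapping.protein_chain(quarter)
            sel = SelectionSpec(chain_id=chain, atom_name="CA")
            cmap = covariance_map(ens, sel, fit_sel=sel, window=fluct_window)
            results["covariance"][quarter] = cmap
            fname = f"covariance_{quarter}.tsv"
            cmap.to_tsv(out_dir / fname)
            written.append(fname)

    # --- manifest ----------------------------------------------------------
    manifest = {
        "inputs": {
            # file names only, so identical runs in different directories
            # produce byte-identical manifests; content is pinned by the
            # checksums below
            "ensemble": Path(config.ensemble_path).name,
            "mapping": Path(config.mapping_path).name,
            "re_name": config.re_name,
            "re_sequence": config.re_sequence,
        },
        "parameters": {
            "cutoff": config.cutoff,
            "occupancy_window": config.occupancy_window,
            "fluctuation_window": config.fluctuation_window,
            "seed": config.seed,
        },
        "n_frames": ens.n_frames,
        "outputs": {
            name: synth.file_checksum(out_dir / name) for name in sorted(written)
        },
        "input_checksums": {
            "ensemble": synth.file_checksum(config.ensemble_path),
            "mapping": synth.file_checksum(config.mapping_path),
        },
    }
    (out_dir / "manifest.json").write_text(
        json.dumps(manifest, indent=2, sort_keys=True) + "\n"
    )
    results["manifest"] = manifest
    return results
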