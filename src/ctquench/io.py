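"""File formats: ensemble/coupling tables, PDB structures, annotation configs.

Tabular data travel as comma-delimited text with ``#``-prefixed header
lines carrying provenance (package version, seed, config hash).  Dimer
structures are written as standard PDB (HETATM records, one chain per
pigment, occupancy 1.00) through gemmi, with the conjugation-path /
overlap-set / ring-frame annotations in a YAML sidecar keyed by atom
serial numbers.
"""
from __future__ import annotations

import io as _io
from pathlib import Path

import gemmi
import numpy as np
import pandas as pd
import yaml

from .descriptors import DimerStructure
from .marcus import StateEnsemble

ENSEMBLE_COLUMNS = ["site", "block", "snapshot", "state", "energy_cm1"]
COUPLING_COLUMNS = ["site", "block", "snapshot", "pair", "coupling_cm1"]

_CHAIN_BY_PIGMENT = {"CHL": "A", "LUT": "B"}


def _write_table(df: pd.DataFrame, path, header: dict | None = None) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    buf = _io.StringIO()
    for key, val in (header or {}).items():
        buf.write(f"# {key}: {val}\n")
    df.to_csv(buf, index=False)
    path.write_text(buf.getvalue())


def _read_table(path) -> pd.DataFrame:
    return pd.read_csv(path, comment="#")


def ensembles_to_frame(ensembles: dict[str, dict[str, StateEnsemble]]) -> pd.DataFrame:
    """Flatten {site: {state: StateEnsemble}} into the tidy ensemble schema."""
    rows = []
    for site, states in ensembles.items():
        for state, ens in states.items():
            rows.append(
                pd.DataFrame(
                    {
                        "site": site,
                        "block": ens.blocks,
                        "snapshot": np.arange(ens.n),
                        "state": state,
                        "energy_cm1": ens.energies,
                    }
                )
            )
    return pd.concat(rows, ignore_index=True)


def frame_to_ensembles(
    df: pd.DataFrame, temperature: float
) -> dict[str, dict[str, StateEnsemble]]:
    missing = set(ENSEMBLE_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"ensemble table missing columns {sorted(missing)}")
    out: dict[str, dict[str, StateEnsemble]] = {}
    for (site, state), grp in df.groupby(["site", "state"], sort=False):
        grp = grp.sort_values("snapshot")
        out.setdefault(site, {})[state] = StateEnsemble(
            state=state,
            energies=grp["energy_cm1"].to_numpy(),
            blocks=grp["block"].to_numpy(),
            site=site,
            temperature=temperature,
        )
    return out


def write_ensembles(ensembles, path, header: dict | None = None) -> None:
    _write_table(ensembles_to_frame(ensembles), path, header)


def read_ensembles(path, temperature: float) -> dict[str, dict[str, StateEnsemble]]:
    return frame_to_ensembles(_read_table(path), temperature)


def couplings_to_frame(
    couplings: dict[str, dict[str, np.ndarray]],
    blocks: dict[str, np.ndarray] | None = None,
) -> pd.DataFrame:
    rows = []
    for site, pairs in couplings.items():
        for pair, samples in pairs.items():
            samples = np.asarray(samples)
            blk = (
                blocks[site]
                if blocks and site in blocks
                else np.zeros(samples.size, dtype=int)
            )
            rows.append(
                pd.DataFrame(
                    {
                        "site": site,
                        "block": blk,
                        "snapshot": np.arange(samples.size),
                        "pair": pair,
                        "coupling_cm1": samples,
                    }
                )
            )
    return pd.concat(rows, ignore_index=True)


def frame_to_couplings(df: pd.DataFrame) -> dict[str, dict[str, np.ndarray]]:
    missing = set(COUPLING_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"coupling table missing columns {sorted(missing)}")
    out: dict[str, dict[str, np.ndarray]] = {}
    for (site, pair), grp in df.groupby(["site", "pair"], sort=False):
        out.setdefault(site, {})[pair] = (
            grp.sort_values("snapshot")["coupling_cm1"].to_numpy()
        )
    return out


def write_couplings(couplings, path, header: dict | None = None, blocks=None) -> None:
    _write_table(couplings_to_frame(couplings, blocks), path, header)


def read_couplings(path) -> dict[str, dict[str, np.ndarray]]:
    return frame_to_couplings(_read_table(path))


def write_table(df: pd.DataFrame, path, header: dict | None = None) -> None:
    """Write any tidy result table with provenance header lines."""
    _write_table(df, path, header)


def read_table(path) -> pd.DataFrame:
    return _read_table(path)


# ---------------------------------------------------------------------------
# structures


def write_structure(structure: DimerStructure, pdb_path, config_path) -> None:
    """Write coordinates as PDB and annotations as a YAML sidecar."""
    st = gemmi.Structure()
    st.name = "ctquench dimer"
    model = gemmi.Model("1")
    chains: dict[str, gemmi.Chain] = {}
    residues: dict[str, gemmi.Residue] = {}
    for pigment in structure.atoms["pigment"].unique():
        chain = gemmi.Chain(_CHAIN_BY_PIGMENT.get(pigment, "X"))
        res = gemmi.Residue()
        res.name = str(pigment)[:3]
        res.seqid = gemmi.SeqId(1, " ")
        res.het_flag = "H"
        chains[pigment] = chain
        residues[pigment] = res
    for row in structure.atoms.itertuples():
        atom = gemmi.Atom()
        atom.name = row.name if hasattr(row, "name") else f"C{row.serial}"
        atom.element = gemmi.Element(row.element)
        atom.pos = gemmi.Position(row.x, row.y, row.z)
        atom.occ = 1.0
        atom.b_iso = 0.0
        atom.serial = int(row.serial)
        residues[row.pigment].add_atom(atom)
    for pigment, chain in chains.items():
        chain.add_residue(residues[pigment])
        model.add_chain(chain)
    st.add_model(model)
    st.setup_entities()
    pdb_path = Path(pdb_path)
    pdb_path.parent.mkdir(parents=True, exist_ok=True)
    st.write_pdb(str(pdb_path))

    config = {
        "paths": {
            pid: [[int(a), int(b), tag] for a, b, tag in bonds]
            for pid, bonds in structure.paths.items()
        },
        "overlap_sets": {
            tag: [int(s) for s in serials]
            for tag, serials in structure.overlap_sets.items()
        },
        "frame_serials": [int(s) for s in structure.frame_serials]
        if structure.frame_serials
        else None,
    }
    Path(config_path).write_text(yaml.safe_dump(config, sort_keys=False))


def read_structure(pdb_path, config_path) -> DimerStructure:
    """Read a PDB + YAML annotation pair back into a DimerStructure."""
    st = gemmi.read_structure(str(pdb_path))
    rows = []
    pigment_by_chain = {v: k for k, v in _CHAIN_BY_PIGMENT.items()}
    for model in st:
        for chain in model:
            for res in chain:
                pigment = pigment_by_chain.get(chain.name, res.name)
                for atom in res:
                    rows.append(
                        {
                            "serial": int(atom.serial),
                            "name": atom.name,
                            "element": atom.element.name,
                            "pigment": pigment,
                            "x": atom.pos.x,
                            "y": atom.pos.y,
                            "z": atom.pos.z,
                        }
                    )
        break  # first model only
    atoms = pd.DataFrame(rows).sort_values("serial").reset_index(drop=True)
    config = yaml.safe_load(Path(config_path).read_text())
    paths = {
        pid: [(int(a), int(b), str(tag)) for a, b, tag in bonds]
        for pid, bonds in config.get("paths", {}).items()
    }
    overlap_sets = {
        tag: [int(s) for s in serials]
        for tag, serials in config.get("overlap_sets", {}).items()
    }
    frame = config.get("frame_serials")
    return DimerStructure(
        atoms=atoms,
        paths=paths,
        overlap_sets=overlap_sets,
        frame_serials=tuple(frame) if frame else None,
    )
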