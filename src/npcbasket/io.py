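"""File formats: crosslink CSV, GMM text tables, bead-model mmCIF, MRC maps,
and the synthetic-bundle directory layout.

Crosslink CSV dialect: header ``protein1,residue1,protein2,residue2,linker``
with 1-based residue indices; duplicate records (unordered) are collapsed
with their multiplicity retained.  GMM text: one component per line,
``weight x y z sigma``.  Bead models are written as mmCIF with one
pseudo-atom per bead (atom ``CA``, residue ``BEA``), the bead radius in the
B-factor field and the bead's residue count in the occupancy field; the
residue seqid is the first residue of the bead's window.
"""

from __future__ import annotations

from pathlib import Path

import gemmi
import numpy as np
import pandas as pd
import yaml

from .assembly import AssemblyState
from .gmm import GaussianMixture
from .representation import apply_symmetry
from .restraints import CrosslinkRecord, PositionalSpec

__all__ = [
    "read_crosslinks",
    "write_crosslinks",
    "read_gmm_text",
    "write_gmm_text",
    "write_model",
    "read_model",
    "write_density",
    "read_density",
    "write_bundle_dir",
    "read_bundle_dir",
]

XL_COLUMNS = ["protein1", "residue1", "protein2", "residue2", "linker"]


# ---------------------------------------------------------------------------
# Crosslink CSV
# ---------------------------------------------------------------------------

def read_crosslinks(path) -> list[CrosslinkRecord]:
    """Read and validate the crosslink CSV dialect.

    Malformed rows raise with their line number; duplicated (unordered)
    records collapse into one with ``multiplicity`` incremented.
    """
    df = pd.read_csv(path, dtype=str)
    if list(df.columns) != XL_COLUMNS:
        raise ValueError(
            f"{path}: expected header {','.join(XL_COLUMNS)}, got {','.join(df.columns)}"
        )
    records: dict[tuple, CrosslinkRecord] = {}
    for pos, row in enumerate(df.itertuples(index=False)):
        line = pos + 2  # header is line 1
        try:
            r1, r2 = int(row.residue1), int(row.residue2)
        except (TypeError, ValueError) as exc:
            raise ValueError(f"{path}:{line}: non-integer residue index") from exc
        if r1 < 1 or r2 < 1:
            raise ValueError(f"{path}:{line}: residue indices are 1-based (got {r1}, {r2})")
        if not row.protein1 or not row.protein2 or pd.isna(row.protein1) or pd.isna(row.protein2):
            raise ValueError(f"{path}:{line}: missing protein name")
        rec = CrosslinkRecord(str(row.protein1), r1, str(row.protein2), r2,
                              str(row.linker))
        key = rec.unordered_key()
        if key in records:
            old = records[key]
            records[key] = CrosslinkRecord(
                old.protein1, old.residue1, old.protein2, old.residue2,
                old.linker, old.multiplicity + 1
            )
        else:
            records[key] = rec
    return list(records.values())


def write_crosslinks(records: list[CrosslinkRecord], path) -> None:
    rows = []
    for rec in records:
        rows.extend(
            [{c: getattr(rec, c) for c in XL_COLUMNS}] * rec.multiplicity
        )
    pd.DataFrame(rows, columns=XL_COLUMNS).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# GMM text
# ---------------------------------------------------------------------------

def write_gmm_text(gmm: GaussianMixture, path) -> None:
    with open(path, "w") as fh:
        fh.write("# weight x y z sigma\n")
        for w, m, s in zip(gmm.weights, gmm.means, gmm.sigmas):
            fh.write(f"{w:.8g} {m[0]:.6f} {m[1]:.6f} {m[2]:.6f} {s:.6f}\n")


def read_gmm_text(path) -> GaussianMixture:
    rows = []
    with open(path) as fh:
        for ln, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split()
            if len(parts) != 5:
                raise ValueError(f"{path}:{ln}: expected 'weight x y z sigma'")
            rows.append([float(p) for p in parts])
    if not rows:
        raise ValueError(f"{path}: no components")
    arr = np.asarray(rows)
    return GaussianMixture(arr[:, 0], arr[:, 1:4], arr[:, 4])


# ---------------------------------------------------------------------------
# Bead models (mmCIF)
# ---------------------------------------------------------------------------

def write_model(state: AssemblyState, path, full_symmetry: int | None = None) -> None:
    """Write one pseudo-atom per coarse bead as mmCIF.

    Chain name is ``subunit.copy`` (suffixed ``.s<k>`` for symmetry images
    when ``full_symmetry`` is given), residue seqid the first residue of the
    bead window, B-factor the bead radius, occupancy the residue count.
    """
    images = apply_symmetry(state, full_symmetry) if full_symmetry else [state]
    st = gemmi.Structure()
    st.name = "beadmodel"
    model = gemmi.Model("1")
    for k, img in enumerate(images):
        suffix = f".s{k}" if full_symmetry else ""
        for ch in img.chains:
            chain = gemmi.Chain(f"{ch.subunit}.{ch.copy_index}{suffix}")
            for b in ch.coarse:
                res = gemmi.Residue()
                res.name = "BEA"
                res.seqid = gemmi.SeqId(int(img.resrange[b, 0]), " ")
                atom = gemmi.Atom()
                atom.name = "CA"
                atom.element = gemmi.Element("C")
                x, y, z = img.coords[b]
                atom.pos = gemmi.Position(x, y, z)
                atom.b_iso = float(img.radii[b])
                atom.occ = float(img.nres[b])
                res.add_atom(atom)
                chain.add_residue(res)
            model.add_chain(chain)
    st.add_model(model)
    st.setup_entities()
    st.make_mmcif_document().write_file(str(path))


def read_model(path) -> AssemblyState:
    """Rebuild an :class:`AssemblyState` from a bead-model mmCIF.

    Rigid-body and role annotations are not stored in the file; the result
    has flexible chains only (sufficient for scoring and analysis).
    """
    st = gemmi.read_structure(str(path))
    chain_beads = []
    for chain in st[0]:
        name = chain.name
        parts = name.split(".")
        subunit, copy_idx = parts[0], int(parts[1]) if len(parts) > 1 else 0
        centers, radii, ranges = [], [], []
        for res in chain:
            atom = res[0]
            centers.append([atom.pos.x, atom.pos.y, atom.pos.z])
            radii.append(atom.b_iso)
            start = res.seqid.num
            ranges.append([start, start + int(round(atom.occ)) - 1])
        chain_beads.append(
            {"subunit": subunit, "copy_index": copy_idx,
             "centers": np.asarray(centers), "radii": np.asarray(radii),
             "resranges": np.asarray(ranges, dtype=np.intp)}
        )
    return AssemblyState.from_chains(chain_beads)


# ---------------------------------------------------------------------------
# Density maps (MRC)
# ---------------------------------------------------------------------------

def write_density(values: np.ndarray, origin, voxel_size: float, path) -> None:
    """Write a voxel map as MRC mode 2 with correct voxel size and origin."""
    values = np.asarray(values, dtype=np.float32)
    if values.ndim != 3 or values.size == 0:
        raise ValueError("density must be a nonempty 3-D grid")
    if voxel_size <= 0:
        raise ValueError("voxel size must be set and positive")
    grid = gemmi.FloatGrid(values)
    nx, ny, nz = values.shape
    grid.unit_cell = gemmi.UnitCell(
        nx * voxel_size, ny * voxel_size, nz * voxel_size, 90, 90, 90
    )
    grid.spacegroup = gemmi.find_spacegroup_by_name("P1")
    ccp4 = gemmi.Ccp4Map()
    ccp4.grid = grid
    ccp4.update_ccp4_header()
    for word, val in zip((50, 51, 52), np.asarray(origin, dtype=float)):
        ccp4.set_header_float(word, val)
    ccp4.write_ccp4_map(str(path))


def read_density(path):
    """Read an MRC map; returns (values, origin, voxel_size)."""
    m = gemmi.read_ccp4_map(str(path))
    values = np.array(m.grid, copy=True)
    origin = np.array([m.header_float(w) for w in (50, 51, 52)])
    voxel = m.grid.unit_cell.a / m.grid.nu
    return values, origin, float(voxel)


# ---------------------------------------------------------------------------
# Synthetic bundle directory
# ---------------------------------------------------------------------------

def _spec_to_dict(spec: PositionalSpec) -> dict:
    d = {
        "kind": spec.kind, "subunit": spec.subunit,
        "res_start": spec.res_start, "res_end": spec.res_end,
        "tolerance": float(spec.tolerance), "copy_index": spec.copy_index,
    }
    if spec.kind == "membrane-slab":
        d["target"] = [float(v) for v in spec.target]
    else:
        d["target"] = [float(v) for v in np.asarray(spec.target)]
    return d


def write_bundle_dir(bundle, out_dir) -> None:
    """Write a synthetic ground-truth bundle as plain-text files."""
    from dataclasses import asdict

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    write_crosslinks(bundle.crosslinks, out / "crosslinks.csv")
    write_gmm_text(bundle.density, out / "density_gmm.txt")
    write_model(bundle.truth_state, out / "truth.cif")
    params = asdict(bundle.params)
    params["anchor_chain_lengths"] = list(params["anchor_chain_lengths"])
    with open(out / "params.yaml", "w") as fh:
        yaml.safe_dump(
            {
                "params": params,
                "seed": bundle.seed,
                "xl_cutoff": bundle.xl_cutoff,
                "em_sigma_scale": bundle.em_sigma_scale,
            },
            fh,
        )
    with open(out / "localizations.yaml", "w") as fh:
        yaml.safe_dump(
            {
                "terminal": [_spec_to_dict(s) for s in bundle.terminal_localizations],
                "membrane": [_spec_to_dict(s) for s in bundle.membrane_anchors],
            },
            fh,
        )


def read_bundle_dir(in_dir):
    """Rebuild a :class:`~npcbasket.synthetic.GroundTruthBundle` from disk.

    The truth state is regenerated deterministically from the echoed params
    (and checked for file presence); crosslinks, density, and localizations
    are read from their files.
    """
    from .synthetic import GroundTruthBundle, GroundTruthParams, make_ground_truth

    src = Path(in_dir)
    for fname in ("params.yaml", "crosslinks.csv", "density_gmm.txt",
                  "localizations.yaml"):
        if not (src / fname).exists():
            raise FileNotFoundError(f"missing bundle file: {src / fname}")
    with open(src / "params.yaml") as fh:
        meta = yaml.safe_load(fh)
    pdict = dict(meta["params"])
    pdict["anchor_chain_lengths"] = tuple(pdict["anchor_chain_lengths"])
    params = GroundTruthParams(**pdict)
    with open(src / "localizations.yaml") as fh:
        locs = yaml.safe_load(fh)
    terminal = [PositionalSpec(**d) for d in locs["terminal"]]
    membrane = [PositionalSpec(**d) for d in locs.get("membrane", [])]
    return GroundTruthBundle(
        truth_state=make_ground_truth(params),
        crosslinks=read_crosslinks(src / "crosslinks.csv"),
        density=read_gmm_text(src / "density_gmm.txt"),
        terminal_localizations=terminal,
        membrane_anchors=membrane,
        params=params,
        seed=meta["seed"],
        xl_cutoff=meta.get("xl_cutoff", 35.0),
        em_sigma_scale=meta.get("em_sigma_scale", 1.0),
    )
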