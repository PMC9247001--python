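"""Crystal structures and methyl probes.

Reads PDB coordinate files, extracts the [13C,1H3]-labeled methyl probes of a
MILVAT-style labeling scheme, combines several conformers into an ensemble and
computes inter-methyl distance tables.  One probe per labeled residue: for Leu
and Val only the proS methyl (delta2 / gamma2) carries the label under the
default scheme, so a single carbon atom represents each probe.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import gemmi
import numpy as np
import pandas as pd

__all__ = [
    "StructureModel",
    "MethylGroup",
    "EnsembleStructure",
    "LabelingScheme",
    "DEFAULT_SCHEME",
    "read_structure",
    "extract_methyls",
    "build_ensemble",
    "methyl_distances",
    "write_methyl_table",
]


@dataclass
class StructureModel:
    """All ATOM records of one coordinate model.

    ``atoms`` columns: chain, residue_number, residue_type, atom_name, x, y, z.
    """

    model_id: str
    atoms: pd.DataFrame

    def __post_init__(self) -> None:
        coords = self.atoms[["x", "y", "z"]].to_numpy(float)
        if not np.all(np.isfinite(coords)):
            raise ValueError(f"model {self.model_id}: non-finite coordinates")
        key = self.atoms[["chain", "residue_number", "atom_name"]]
        dup = key[key.duplicated()]
        if len(dup):
            row = dup.iloc[0]
            raise ValueError(
                f"model {self.model_id}: duplicate atom record "
                f"{row.chain}/{row.residue_number}/{row.atom_name}"
            )

    def chains(self) -> list[str]:
        return list(dict.fromkeys(self.atoms["chain"]))


@dataclass
class MethylGroup:
    """One labeled methyl probe identified by its carbon atom."""

    residue_number: int
    residue_type: str  # 3-letter code
    methyl_id: str  # e.g. "Leu-d2"
    stereo: str  # proS | proR | n/a
    carbon_position: np.ndarray  # (3,) Angstrom
    pseudo_proton_position: np.ndarray | None = None

    @property
    def key(self) -> str:
        return f"{self.residue_type}{self.residue_number}-{self.methyl_id.split('-')[-1]}"


@dataclass
class EnsembleStructure:
    """Conformers sharing a common set of methyl probes.

    ``common_atoms`` maps a methyl key to the per-model coordinate array, in
    input model order.
    """

    models: list[StructureModel]
    common_atoms: dict[str, np.ndarray] = field(default_factory=dict)
    methyls_per_model: list[list[MethylGroup]] = field(default_factory=list)

    @property
    def n_models(self) -> int:
        return len(self.models)

    def coordinates(self, keys: list[str] | None = None) -> np.ndarray:
        """(n_models, n_probes, 3) array over the common methyls."""
        keys = list(self.common_atoms) if keys is None else keys
        return np.stack([self.common_atoms[k] for k in keys], axis=1)


# (residue type, labeled carbon, methyl id, stereo) for the MIL(proS)V(proS)AT
# scheme.  Ile is labeled at delta1 by default; the gamma2 alternative is
# available through LabelingScheme(ile_position="g1").
_METHYL_ATOMS = {
    "ALA": ("CB", "Ala-b", "n/a"),
    "ILE": ("CD1", "Ile-d1", "n/a"),
    "LEU": ("CD2", "Leu-d2", "proS"),
    "VAL": ("CG2", "Val-g2", "proS"),
    "MET": ("CE", "Met-e", "n/a"),
    "THR": ("CG2", "Thr-g2", "n/a"),
}

_ILE_G2 = ("CG2", "Ile-g2", "n/a")  # Ile's other methyl; CG1 is a methylene

_ONE_LETTER = {"ALA": "A", "ILE": "I", "LEU": "L", "VAL": "V", "MET": "M", "THR": "T"}
_FROM_ONE = {v: k for k, v in _ONE_LETTER.items()}


@dataclass(frozen=True)
class LabelingScheme:
    """Which residue types carry a labeled methyl, and where.

    ``types`` holds 3-letter residue codes.  ``ile_position`` selects the Ile
    probe carbon: "d1" (CD1, the scheme used for sample preparation) or "g2"
    (CG2).
    """

    types: tuple[str, ...] = ("MET", "ILE", "LEU", "VAL", "ALA", "THR")
    ile_position: str = "d1"

    def __post_init__(self) -> None:
        for t in self.types:
            if t not in _METHYL_ATOMS:
                raise ValueError(f"unknown residue type in labeling scheme: {t!r}")
        if self.ile_position not in ("d1", "g2"):
            raise ValueError(f"ile_position must be 'd1' or 'g2', got {self.ile_position!r}")

    @classmethod
    def from_string(cls, spec: str) -> "LabelingScheme":
        """Parse a compact scheme string such as ``MILpSVpSAT`` or ``ILV``."""
        letters = []
        for ch in spec.replace("pS", "").replace("proS", ""):
            if ch.upper() not in _FROM_ONE:
                raise ValueError(f"unknown residue letter {ch!r} in scheme {spec!r}")
            letters.append(_FROM_ONE[ch.upper()])
        return cls(types=tuple(dict.fromkeys(letters)))

    def probe_atom(self, residue_type: str) -> tuple[str, str, str]:
        if residue_type == "ILE" and self.ile_position == "g2":
            return _ILE_G2
        return _METHYL_ATOMS[residue_type]


DEFAULT_SCHEME = LabelingScheme()


def read_structure(path: str) -> list[StructureModel]:
    """Read a PDB file into one :class:`StructureModel` per MODEL record.

    Alternate locations keep the highest-occupancy conformer.  Raises
    ``ValueError`` for unparsable or empty files, naming the offender.
    """
    try:
        st = gemmi.read_pdb(str(path))
    except (RuntimeError, ValueError) as exc:  # gemmi reports the bad line
        raise ValueError(f"cannot parse PDB file {path}: {exc}") from exc
    st.remove_alternative_conformations()
    models: list[StructureModel] = []
    for model in st:
        rows = []
        for chain in model:
            for res in chain:
                for atom in res:
                    rows.append(
                        (
                            chain.name,
                            res.seqid.num,
                            res.name.upper(),
                            atom.name,
                            atom.pos.x,
                            atom.pos.y,
                            atom.pos.z,
                        )
                    )
        if not rows:
            continue
        atoms = pd.DataFrame(
            rows, columns=["chain", "residue_number", "residue_type", "atom_name", "x", "y", "z"]
        )
        models.append(StructureModel(model_id=str(model.num), atoms=atoms))
    if not models:
        raise ValueError(f"no ATOM records found in {path}")
    return models


def extract_methyls(
    model: StructureModel,
    scheme: LabelingScheme = DEFAULT_SCHEME,
    chain: str | None = None,
) -> tuple[list[MethylGroup], list[dict]]:
    """Extract one methyl probe per labeled residue.

    Returns ``(methyls, report)``; the report lists labeled residues whose
    probe carbon is missing from the coordinates (never silently dropped).
    Defaults to the first chain when ``chain`` is None.
    """
    chains = model.chains()
    if chain is None:
        chain = chains[0]
    elif chain not in chains:
        raise ValueError(f"chain {chain!r} not in model (has {chains})")
    atoms = model.atoms[model.atoms["chain"] == chain]
    methyls: list[MethylGroup] = []
    report: list[dict] = []
    for (resnum, restype), group in sorted(
        atoms.groupby(["residue_number", "residue_type"], sort=False),
        key=lambda kv: kv[0][0],
    ):
        if restype not in scheme.types:
            continue
        atom_name, methyl_id, stereo = scheme.probe_atom(restype)
        hit = group[group["atom_name"] == atom_name]
        if len(hit) == 0:
            report.append(
                {
                    "residue_number": int(resnum),
                    "residue_type": restype,
                    "missing_atom": atom_name,
                }
            )
            continue
        xyz = hit.iloc[0][["x", "y", "z"]].to_numpy(float)
        methyls.append(
            MethylGroup(
                residue_number=int(resnum),
                residue_type=restype,
                methyl_id=methyl_id,
                stereo=stereo,
                carbon_position=xyz,
            )
        )
    return methyls, report


def build_ensemble(
    models: list[StructureModel],
    scheme: LabelingScheme = DEFAULT_SCHEME,
    chain: str | None = None,
) -> EnsembleStructure:
    """Combine conformers; ``common_atoms`` keeps methyls present in every model."""
    if not models:
        raise ValueError("build_ensemble requires at least one model")
    per_model: list[dict[str, MethylGroup]] = []
    for m in models:
        methyls, _ = extract_methyls(m, scheme, chain=chain)
        per_model.append({g.key: g for g in methyls})
    common = set(per_model[0])
    for d in per_model[1:]:
        common &= set(d)
    if not common:
        raise ValueError("no methyl probes common to all models")
    order = [k for k in per_model[0] if k in common]
    common_atoms = {
        k: np.stack([d[k].carbon_position for d in per_model]) for k in order
    }
    return EnsembleStructure(
        models=list(models),
        common_atoms=common_atoms,
        methyls_per_model=[list(d.values()) for d in per_model],
    )


def methyl_distances(methyls: list[MethylGroup]) -> pd.DataFrame:
    """Symmetric carbon-carbon distance table (Angstrom), zero diagonal."""
    if not methyls:
        raise ValueError("no methyls given")
    keys = [g.key for g in methyls]
    coords = np.stack([g.carbon_position for g in methyls])
    diff = coords[:, None, :] - coords[None, :, :]
    dist = np.sqrt((diff**2).sum(-1))
    return pd.DataFrame(dist, index=keys, columns=keys)


def write_methyl_table(methyls: list[MethylGroup], path: str) -> None:
    """TSV export: residue_number, residue_type, methyl_id, stereo, x, y, z."""
    rows = [
        {
            "residue_number": g.residue_number,
            "residue_type": g.residue_type,
            "methyl_id": g.methyl_id,
            "stereo": g.stereo,
            "x": g.carbon_position[0],
            "y": g.carbon_position[1],
            "z": g.carbon_position[2],
        }
        for g in methyls
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
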