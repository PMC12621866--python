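"""Shared readers and writers: FASTA, PDB atoms, pipeline config.

All tabular formats are plain tab-separated text with '#'-prefixed
headers, UTF-8, '.' decimal separator, so outputs are bit-identical
across platforms.  Coordinates and indices are 0-based internally;
intervals are half-open.
"""

from __future__ import annotations

import logging
from dataclasses import fields as dataclass_fields
from typing import Dict, List, Optional, Sequence

import yaml
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord as BioSeqRecord
from Bio.SeqIO.FastaIO import FastaWriter

from foldcensus.annotation import AnnotationConfig
from foldcensus.biophys import (
    AtomRecord,
    DEFAULT_VDW_RADIUS,
    SasaParams,
    VDW_RADII,
)
from foldcensus.filters import FilterConfig
from foldcensus.sampling import SamplingParams, SequenceRecord

logger = logging.getLogger(__name__)


def _params_description(params: Optional[SamplingParams]) -> str:
    if params is None:
        return ""
    return " ".join(
        f"{k}={getattr(params, k)}"
        for k in (
            "temperature", "top_k", "top_p", "repetition_penalty",
            "max_tokens", "max_residues", "seed",
        )
    )


def write_fasta(records: Sequence[SequenceRecord], path) -> None:
    """Write records with 80-column wrapping; sampling parameters are
    encoded in the description line as key=value pairs."""
    bio = []
    for rec in records:
        desc = rec.description or _params_description(rec.params)
        if rec.source:
            desc = f"source={rec.source} {desc}".strip()
        bio.append(BioSeqRecord(Seq(rec.sequence), id=rec.id, description=desc))
    with open(path, "w") as fh:
        FastaWriter(fh, wrap=80).write_file(bio)


def read_fasta(path) -> List[SequenceRecord]:
    """Read FASTA into records; ids, descriptions and sequences are
    preserved and CRLF line endings normalized by the parser."""
    out = []
    for rec in SeqIO.parse(str(path), "fasta"):
        desc = rec.description
        if desc.startswith(rec.id):
            desc = desc[len(rec.id):].strip()
        source = ""
        for tok in desc.split():
            if tok.startswith("source="):
                source = tok[len("source="):]
        out.append(
            SequenceRecord(
                id=rec.id, sequence=str(rec.seq).upper(),
                source=source, description=desc,
            )
        )
    return out


def read_pdb_atoms(path) -> List[AtomRecord]:
    """Parse ATOM records of model 1 (altloc blank or 'A'), heavy atoms
    only, via biotite; elements fall back to the atom-name initial when
    the element columns are blank."""
    import biotite.structure.io.pdb as pdb

    pdb_file = pdb.PDBFile.read(str(path))
    try:
        structure = pdb_file.get_structure(model=1, altloc="first")
    except Exception as exc:
        raise ValueError(f"{path}: cannot parse coordinates ({exc})") from exc
    atoms: List[AtomRecord] = []
    for i in range(structure.array_length()):
        if structure.hetero[i]:
            continue
        element = (structure.element[i] or "").strip().upper()
        if not element:
            element = structure.atom_name[i].strip()[:1].upper()
        if element == "H":
            continue
        atoms.append(
            AtomRecord(
                residue_index=int(structure.res_id[i]),
                residue_name=str(structure.res_name[i]),
                element=element,
                coords=tuple(float(c) for c in structure.coord[i]),
                vdw_radius=VDW_RADII.get(element, DEFAULT_VDW_RADIUS),
            )
        )
    if not atoms:
        logger.warning("%s: no ATOM records parsed", path)
    return atoms


# ---------------------------------------------------------------------------
# Pipeline configuration
# ---------------------------------------------------------------------------

_SECTION_TYPES = {
    "filter": FilterConfig,
    "annotation": AnnotationConfig,
    "sasa": SasaParams,
    "sampling": SamplingParams,
}


class PipelineConfig:
    """All module configurations in one human-readable YAML document.

    Unknown keys are rejected so a typo cannot silently fall back to a
    default; every threshold is echoed into reports for provenance.
    """

    def __init__(self, filter=None, annotation=None, sasa=None, sampling=None,
                 evalue_max: float = 0.01, seed: int = 0):
        self.filter = filter or FilterConfig()
        self.annotation = annotation or AnnotationConfig()
        self.sasa = sasa or SasaParams()
        self.sampling = sampling or SamplingParams()
        self.evalue_max = evalue_max
        self.seed = seed

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known_top = set(_SECTION_TYPES) | {"evalue_max", "seed"}
        unknown = set(raw) - known_top
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        kwargs = {}
        for section, typ in _SECTION_TYPES.items():
            if section in raw:
                allowed = {f.name for f in dataclass_fields(typ)}
                bad = set(raw[section]) - allowed
                if bad:
                    raise ValueError(
                        f"unknown keys in [{section}]: {sorted(bad)}"
                    )
                sec = dict(raw[section])
                if section == "filter" and "forbidden_letters" in sec:
                    sec["forbidden_letters"] = frozenset(sec["forbidden_letters"])
                kwargs[section] = typ(**sec)
        return cls(
            evalue_max=raw.get("evalue_max", 0.01),
            seed=raw.get("seed", 0),
            **kwargs,
        )

    def provenance(self) -> Dict:
        """Every threshold, for echoing into reports."""
        return {
            "filter": {
                "forbidden_letters": "".join(sorted(self.filter.forbidden_letters)),
                "max_length": self.filter.max_length,
                "max_single_aa_fraction": self.filter.max_single_aa_fraction,
            },
            "annotation": {
                "tm_min": self.annotation.tm_min,
                "cov_min": self.annotation.cov_min,
                "coverage_rule": self.annotation.coverage_rule,
            },
            "sasa": {
                "probe_radius": self.sasa.probe_radius,
                "n_sphere_points": self.sasa.n_sphere_points,
            },
            "evalue_max": self.evalue_max,
            "seed": self.seed,
        }
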