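"""Metabolic model I/O: SBML and toy-table loading, irreversible expansion,
and transport-matrix extraction.

A genome-scale model enters as a stoichiometric matrix ``S`` (metabolites x
reactions).  Every reversible reaction is duplicated into a forward and a
reverse column so that all fluxes are nonnegative, and the rows of the
expanded matrix that correspond to monitored extracellular species (plus a
synthesized biomass row) form the transport matrix ``T`` that maps a flux
vector to rates of change of measurable concentrations.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp

logger = logging.getLogger(__name__)

BIOMASS_SPECIES = "biomass"

__all__ = [
    "BIOMASS_SPECIES",
    "GenomeScaleModel",
    "IrreversibleModel",
    "TransportMatrix",
    "load_model",
    "load_toy_table",
    "write_toy_table",
    "split_reversible",
    "build_transport",
]


class ModelFormatError(ValueError):
    """Raised when a model file cannot be interpreted."""


@dataclass
class GenomeScaleModel:
    """Stoichiometric model as loaded, before irreversible expansion.

    ``S`` is metabolites x reactions; ``compartments`` tags each metabolite
    (extracellular compartments listed in ``extracellular``); ``reversible``
    flags each reaction.
    """

    metabolite_ids: list[str]
    reaction_ids: list[str]
    S: sp.csc_matrix
    reversible: np.ndarray
    compartments: list[str]
    biomass_reaction_id: str
    gene_count: int = 0
    extracellular: frozenset[str] = frozenset({"e"})

    def __post_init__(self) -> None:
        n_met, n_rxn = self.S.shape
        if n_met != len(self.metabolite_ids) or n_rxn != len(self.reaction_ids):
            raise ModelFormatError(
                f"S shape {self.S.shape} does not match "
                f"{len(self.metabolite_ids)} metabolites x "
                f"{len(self.reaction_ids)} reactions"
            )
        if self.biomass_reaction_id not in self.reaction_ids:
            raise ModelFormatError(
                f"biomass reaction {self.biomass_reaction_id!r} not in model"
            )
        if len(self.compartments) != n_met:
            raise ModelFormatError("one compartment tag required per metabolite")

    @property
    def n_reversible(self) -> int:
        return int(np.sum(self.reversible))

    def is_extracellular(self, met_index: int) -> bool:
        return self.compartments[met_index] in self.extracellular


@dataclass
class IrreversibleModel:
    """Model after duplicating reversible reactions (forward + reverse).

    ``origin_map[j] = (original reaction id, 'forward'|'reverse')`` for each
    expanded column j.  Reverse columns carry the negated coefficients of
    their forward partner and are named ``<id>_rev``.
    """

    metabolite_ids: list[str]
    reaction_ids: list[str]
    S: sp.csc_matrix
    origin_map: list[tuple[str, str]]
    compartments: list[str]
    biomass_reaction_id: str
    extracellular: frozenset[str] = frozenset({"e"})

    @property
    def n_reactions(self) -> int:
        return len(self.reaction_ids)

    def is_extracellular(self, met_index: int) -> bool:
        return self.compartments[met_index] in self.extracellular

    def internal_stoichiometry(self) -> sp.csr_matrix:
        """Rows of the expanded S for internal (non-extracellular) metabolites.

        This is the matrix whose null space encodes the intracellular
        steady-state constraint S.V = 0; extracellular rows are excluded
        because their dynamics are carried by the transport update, not by
        a steady-state assumption (for models with explicit exchange
        reactions the two readings coincide).
        """
        keep = [i for i in range(len(self.metabolite_ids))
                if not self.is_extracellular(i)]
        return sp.csr_matrix(self.S)[keep, :]


@dataclass
class TransportMatrix:
    """Rows of the expanded S for monitored external species plus biomass.

    Entries are signed stoichiometric coefficients: negative for uptake
    (inward) columns, positive for secretion and for the biomass column.
    """

    species_ids: list[str]
    T: np.ndarray
    reaction_ids: list[str] = field(default_factory=list)

    @property
    def biomass_index(self) -> int:
        return self.species_ids.index(BIOMASS_SPECIES)

    @property
    def n_species(self) -> int:
        return len(self.species_ids)


# ---------------------------------------------------------------------------
# loading

def load_model(path: str, fmt: str | None = None) -> GenomeScaleModel:
    """Load a metabolic model from SBML or from the toy-table format.

    ``fmt`` is ``"sbml"`` or ``"toy-table"``; when omitted it is inferred
    from the file suffix (``.xml``/``.sbml`` -> SBML, anything else toy).
    """
    if fmt is None:
        fmt = "sbml" if str(path).endswith((".xml", ".sbml", ".xml.gz")) else "toy-table"
    if fmt == "sbml":
        return _load_sbml(path)
    if fmt == "toy-table":
        return load_toy_table(path)
    raise ValueError(f"unknown model format {fmt!r}")


def _load_sbml(path: str) -> GenomeScaleModel:
    import cobra.io

    try:
        cm = cobra.io.read_sbml_model(str(path))
    except Exception as exc:  # cobra raises several parser exception types
        raise ModelFormatError(f"cannot parse SBML file {path}: {exc}") from exc
    return from_cobra(cm)


def from_cobra(cm) -> GenomeScaleModel:
    """Convert a cobra model (matrix, reversibility, compartments, biomass)."""
    met_ids = [m.id for m in cm.metabolites]
    rxn_ids = [r.id for r in cm.reactions]
    met_index = {m: i for i, m in enumerate(met_ids)}
    rows, cols, vals = [], [], []
    for j, r in enumerate(cm.reactions):
        for met, coef in r.metabolites.items():
            rows.append(met_index[met.id])
            cols.append(j)
            vals.append(float(coef))
    S = sp.csc_matrix((vals, (rows, cols)), shape=(len(met_ids), len(rxn_ids)))
    reversible = np.array([r.lower_bound < 0 for r in cm.reactions], dtype=bool)
    compartments = [m.compartment for m in cm.metabolites]
    biomass = _find_biomass(cm, rxn_ids)
    model = GenomeScaleModel(
        metabolite_ids=met_ids,
        reaction_ids=rxn_ids,
        S=S,
        reversible=reversible,
        compartments=compartments,
        biomass_reaction_id=biomass,
        gene_count=len(cm.genes),
    )
    logger.info(
        "loaded model: %d metabolites, %d reactions, %d genes",
        len(met_ids), len(rxn_ids), model.gene_count,
    )
    return model


def _find_biomass(cm, rxn_ids: list[str]) -> str:
    # objective first, then BiGG naming conventions
    try:
        from cobra.util.solver import linear_reaction_coefficients

        coefs = linear_reaction_coefficients(cm)
        if coefs:
            return next(iter(coefs)).id
    except Exception:
        pass
    candidates = [r for r in rxn_ids if "biomass" in r.lower() or "growth" in r.lower()]
    if not candidates:
        raise ModelFormatError("no biomass reaction found (no objective, no "
                               "reaction id containing 'biomass'/'growth')")
    return candidates[0]


# ---------------------------------------------------------------------------
# toy-table format
#
# Plain delimited text with three sections:
#   [metabolites]      id  compartment
#   [reactions]        id  reversible(0/1)  biomass(0/1)
#   [stoichiometry]    metabolite  reaction  coefficient
# '#' starts a comment; fields are whitespace-separated.

def load_toy_table(path: str) -> GenomeScaleModel:
    sections: dict[str, list[list[str]]] = {}
    current: str | None = None
    with open(path) as fh:
        for ln, raw in enumerate(fh, 1):
            line = raw.split("#", 1)[0].strip()
            if not line:
                continue
            if line.startswith("[") and line.endswith("]"):
                current = line[1:-1].strip().lower()
                sections[current] = []
                continue
            if current is None:
                raise ModelFormatError(f"{path}:{ln}: data before any [section]")
            sections[current].append(line.split())

    for sec in ("metabolites", "reactions", "stoichiometry"):
        if sec not in sections:
            raise ModelFormatError(f"{path}: missing [{sec}] section")

    met_ids, compartments = [], []
    for row in sections["metabolites"]:
        if len(row) != 2:
            raise ModelFormatError(f"{path}: bad metabolite row {row!r}")
        met_ids.append(row[0])
        compartments.append(row[1])

    rxn_ids, reversible, biomass_flags = [], [], []
    for row in sections["reactions"]:
        if len(row) != 3:
            raise ModelFormatError(f"{path}: bad reaction row {row!r}")
        rxn_ids.append(row[0])
        reversible.append(bool(int(row[1])))
        biomass_flags.append(bool(int(row[2])))
    if sum(biomass_flags) != 1:
        raise ModelFormatError(
            f"{path}: exactly one reaction must carry the biomass flag "
            f"(found {sum(biomass_flags)})"
        )
    biomass_id = rxn_ids[biomass_flags.index(True)]

    met_index = {m: i for i, m in enumerate(met_ids)}
    rxn_index = {r: j for j, r in enumerate(rxn_ids)}
    rows, cols, vals = [], [], []
    for row in sections["stoichiometry"]:
        if len(row) != 3:
            raise ModelFormatError(f"{path}: bad stoichiometry row {row!r}")
        met, rxn, coef = row
        if met not in met_index:
            raise ModelFormatError(f"{path}: unknown metabolite {met!r}")
        if rxn not in rxn_index:
            raise ModelFormatError(f"{path}: unknown reaction {rxn!r}")
        rows.append(met_index[met])
        cols.append(rxn_index[rxn])
        vals.append(float(coef))
    S = sp.csc_matrix((vals, (rows, cols)), shape=(len(met_ids), len(rxn_ids)))
    return GenomeScaleModel(
        metabolite_ids=met_ids,
        reaction_ids=rxn_ids,
        S=S,
        reversible=np.asarray(reversible, dtype=bool),
        compartments=compartments,
        biomass_reaction_id=biomass_id,
    )


def write_toy_table(model: GenomeScaleModel, path: str) -> None:
    """Write a model in the toy-table format (round-trips exactly)."""
    S = sp.coo_matrix(model.S)
    with open(path, "w") as fh:
        fh.write("[metabolites]\n")
        for m, c in zip(model.metabolite_ids, model.compartments):
            fh.write(f"{m}\t{c}\n")
        fh.write("[reactions]\n")
        for r, rev in zip(model.reaction_ids, model.reversible):
            bio = int(r == model.biomass_reaction_id)
            fh.write(f"{r}\t{int(rev)}\t{bio}\n")
        fh.write("[stoichiometry]\n")
        for i, j, v in sorted(zip(S.row, S.col, S.data), key=lambda t: (t[1], t[0])):
            fh.write(f"{model.metabolite_ids[i]}\t{model.reaction_ids[j]}\t{float(v)!r}\n")


# ---------------------------------------------------------------------------
# irreversible expansion and transport extraction

def split_reversible(model: GenomeScaleModel) -> IrreversibleModel:
    """Duplicate every reversible reaction into a forward/reverse pair.

    Forward columns keep the original order and ids; reverse columns (the
    negated coefficient vectors, named ``<id>_rev``) are appended after
    them, so the expanded column count is r + r_rev.
    """
    S = sp.csc_matrix(model.S)
    rev_idx = np.flatnonzero(model.reversible)
    S_rev = -S[:, rev_idx]
    S_exp = sp.hstack([S, S_rev], format="csc") if len(rev_idx) else S
    rxn_ids = list(model.reaction_ids) + [
        f"{model.reaction_ids[j]}_rev" for j in rev_idx
    ]
    origin = [(r, "forward") for r in model.reaction_ids] + [
        (model.reaction_ids[j], "reverse") for j in rev_idx
    ]
    return IrreversibleModel(
        metabolite_ids=list(model.metabolite_ids),
        reaction_ids=rxn_ids,
        S=S_exp,
        origin_map=origin,
        compartments=list(model.compartments),
        biomass_reaction_id=model.biomass_reaction_id,
        extracellular=model.extracellular,
    )


def build_transport(
    model: IrreversibleModel,
    monitored: list[str],
    mapping: dict[str, str] | None = None,
) -> TransportMatrix:
    """Extract the transport matrix over monitored external species.

    ``monitored`` lists species in the desired row order; each entry either
    equals an extracellular metabolite id of the model, is mapped to one via
    ``mapping``, or is the biomass pseudo-species (``"biomass"``).  The
    biomass row is synthesized with +1 at the biomass reaction column (and
    -1 at its reverse partner if one exists): genome-scale models carry no
    biomass species row, and this makes the Euler update treat biomass like
    any other monitored concentration.
    """
    mapping = mapping or {}
    met_index = {m: i for i, m in enumerate(model.metabolite_ids)}
    S = sp.csr_matrix(model.S)
    n_rxn = model.n_reactions
    rows = np.zeros((len(monitored), n_rxn))
    seen_biomass = 0
    for i, species in enumerate(monitored):
        if species == BIOMASS_SPECIES:
            j = model.reaction_ids.index(model.biomass_reaction_id)
            rows[i, j] = 1.0
            rev_id = f"{model.biomass_reaction_id}_rev"
            if rev_id in model.reaction_ids:
                rows[i, model.reaction_ids.index(rev_id)] = -1.0
            seen_biomass += 1
            continue
        met = mapping.get(species, species)
        if met not in met_index:
            candidates = [m for m in model.metabolite_ids
                          if species.lower() in m.lower()][:10]
            raise KeyError(
                f"monitored species {species!r} does not map to a model "
                f"metabolite; candidates: {candidates}"
            )
        k = met_index[met]
        if not model.is_extracellular(k):
            raise ValueError(
                f"monitored species {species!r} maps to metabolite {met!r} in "
                f"internal compartment {model.compartments[k]!r}"
            )
        rows[i, :] = S[k, :].toarray().ravel()
    if seen_biomass != 1:
        raise ValueError(
            f"monitored list must contain the biomass pseudo-species exactly "
            f"once (found {seen_biomass})"
        )
    return TransportMatrix(species_ids=list(monitored), T=rows,
                           reaction_ids=list(model.reaction_ids))
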