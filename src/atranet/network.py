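"""Network assembly: genes, promoter edges, global parameters, knockouts.

The model couples three layers: a *signal initiation* layer (Trigger = the
ligand-bound RAR/RXR complex, the BLR1/CXCR5 receptor whose protein stands in
for the signalsome, and cRaf whose S621-phosphorylated form reports MAPK
activity), a *signal integration* layer of myelomonocytic transcription
factors, and a *phenotype* layer of differentiation markers.  Promoter edges
are signed, weighted Hill interactions; the signed connectivity of the
integration and phenotype layers follows the curated myelomonocytic
transcription-factor wiring, and the positive-feedback closure of the
initiation layer (activated Trigger and cRaf-pS621 driving the BLR1 promoter)
carries its own edges.
"""

from __future__ import annotations

import copy as _copy
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import yaml

from .constants import AVOGADRO, cell_volume_liters

__all__ = [
    "NetworkValidationError",
    "GeneRecord",
    "RegulatoryInteraction",
    "GlobalParameters",
    "NetworkModel",
    "MODULES",
    "SIGNAL_SPECIES",
    "load_network",
    "default_network",
    "initiation_submodel",
    "count_state_equations",
    "apply_gene_knockout",
    "apply_connection_knockout",
    "copies_to_concentration",
    "concentration_to_copies",
]

MODULES = ("initiation", "integration", "phenotype")

#: activated species of the signal-initiation layer, in state order
SIGNAL_SPECIES = ("Trigger_active", "signalsome", "cRaf_pS621")


class NetworkValidationError(ValueError):
    """Raised when a network configuration fails validation.

    Carries every problem found, so a malformed configuration never yields a
    partially built model.
    """

    def __init__(self, problems: Sequence[str]):
        self.problems = list(problems)
        super().__init__("invalid network configuration:\n  - " + "\n  - ".join(self.problems))


@dataclass(frozen=True)
class GeneRecord:
    """One gene: sequence lengths, copy number, module assignment.

    ``basal_weight`` is the constitutive promoter-configuration weight W_R1
    of the gene (dimensionless); ``pretreatment_scale`` optionally records a
    literature estimate of the protein concentration before treatment (nM).
    """

    name: str
    gene_length_nt: float
    transcript_length_nt: float
    protein_length_aa: float
    gene_copies: float = 2.0
    module: str = "integration"
    basal_weight: float = 0.0
    pretreatment_scale: float | None = None

    def validate(self) -> list[str]:
        problems = []
        if self.gene_length_nt <= 0:
            problems.append(f"gene {self.name}: gene_length_nt must be > 0")
        if self.transcript_length_nt <= 0:
            problems.append(f"gene {self.name}: transcript_length_nt must be > 0")
        if self.protein_length_aa <= 0:
            problems.append(f"gene {self.name}: protein_length_aa must be > 0")
        if self.gene_copies < 0:
            problems.append(f"gene {self.name}: gene_copies must be >= 0")
        if self.module not in MODULES:
            problems.append(f"gene {self.name}: unknown module {self.module!r}")
        if self.basal_weight < 0:
            problems.append(f"gene {self.name}: basal_weight must be >= 0")
        if self.pretreatment_scale is not None and self.pretreatment_scale <= 0:
            problems.append(f"gene {self.name}: pretreatment_scale must be > 0")
        return problems


@dataclass(frozen=True)
class RegulatoryInteraction:
    """One signed, weighted effector -> target promoter edge.

    The effector is either a gene (its protein level, nM, feeds the Hill
    transfer function) or one of the activated signaling species.  Activation
    edges contribute to both numerator and denominator of the promoter
    control term; repression edges to the denominator only.
    """

    effector: str
    target: str
    sign: str  # "activation" | "repression"
    weight: float
    half_saturation: float  # K_ij, nM
    cooperativity: float    # eta_ij
    source: str = "table"   # "table" | "curated" | "initiation"

    def validate(self) -> list[str]:
        label = f"edge {self.effector}->{self.target}"
        problems = []
        if self.sign not in ("activation", "repression"):
            problems.append(f"{label}: sign must be activation|repression, got {self.sign!r}")
        if not (0.0 <= self.weight <= 100.0):
            problems.append(f"{label}: weight {self.weight} outside [0, 100]")
        if not (0.0 < self.half_saturation <= 1000.0):
            problems.append(f"{label}: half_saturation {self.half_saturation} outside (0, 1000] nM")
        if not (0.0 < self.cooperativity <= 4.0):
            problems.append(f"{label}: cooperativity {self.cooperativity} outside (0, 4]")
        return problems


@dataclass(frozen=True)
class GlobalParameters:
    """Characteristic cell-scale parameters shared by every gene.

    Units: copies/cell for machinery abundances and saturation constants,
    hr^-1 for rate constants, nt for lengths, nM for signaling affinities,
    uM^-1 for the ATRA gain, um for the cell diameter.
    """

    rnap_copies: float = 85_000.0       # R1
    ribosome_copies: float = 1.0e6      # R2
    K_T: float = 95_000.0               # transcription saturation, copies/cell
    K_X: float = 600.0                  # translation saturation, copies/cell
    theta_m: float = 0.34               # hr^-1
    theta_p: float = 0.07               # hr^-1
    mu: float = 0.035                   # hr^-1
    k_d_fraction: float = 0.10          # k_d = k_d_fraction * mu
    k_T: float = 1.44                   # hr^-1
    k_X: float = 3.60                   # hr^-1
    L_T0: float = 44_192.0              # nt, characteristic gene length
    L_X0: float = 1_374.0               # nt, characteristic transcript length
    k_act_craf: float = 1.0             # hr^-1, k+,cRaf
    K_act_craf: float = 60.0            # nM, K+,cRaf
    K_D: float = 10.0                   # nM, MAPK inhibitor affinity
    k_signalsome: float = 0.0385        # hr^-1, signalsome formation from BLR1 protein
    alpha_gain: float = 0.1             # uM^-1, applied only above atra_threshold
    atra_threshold: float = 0.25        # uM
    cell_diameter_um: float = 12.4
    cytoplasm_fraction: float = 0.51

    @property
    def k_d(self) -> float:
        """Non-specific decay constant of activated species, hr^-1."""
        return self.k_d_fraction * self.mu

    @property
    def volume_liters(self) -> float:
        return cell_volume_liters(self.cell_diameter_um, self.cytoplasm_fraction)

    @property
    def nM_per_copy(self) -> float:
        return 1e9 / (AVOGADRO * self.volume_liters)

    def validate(self) -> list[str]:
        problems = []
        nonneg = (
            "rnap_copies", "ribosome_copies", "K_T", "K_X", "theta_m", "theta_p",
            "mu", "k_d_fraction", "k_T", "k_X", "L_T0", "L_X0", "k_act_craf",
            "K_act_craf", "K_D", "k_signalsome", "alpha_gain", "atra_threshold",
        )
        for name in nonneg:
            if getattr(self, name) < 0:
                problems.append(f"parameter {name} must be >= 0")
        if not (0.0 < self.cytoplasm_fraction <= 1.0):
            problems.append("parameter cytoplasm_fraction must be in (0, 1]")
        if self.cell_diameter_um <= 0:
            problems.append("parameter cell_diameter_um must be > 0")
        return problems


@dataclass
class NetworkModel:
    """Validated network: genes, promoter edges and global parameters."""

    genes: list[GeneRecord]
    interactions: list[RegulatoryInteraction]
    parameters: GlobalParameters = field(default_factory=GlobalParameters)

    # --- rosters -----------------------------------------------------------
    @property
    def gene_names(self) -> list[str]:
        return [g.name for g in self.genes]

    def gene(self, name: str) -> GeneRecord:
        for g in self.genes:
            if g.name == name:
                return g
        raise KeyError(f"unknown gene {name!r}")

    def gene_index(self, name: str) -> int:
        for i, g in enumerate(self.genes):
            if g.name == name:
                return i
        raise KeyError(f"unknown gene {name!r}")

    @property
    def state_index(self) -> dict[str, int]:
        """Ordered bijection observable-name -> state position.

        Layout: all mRNAs in gene order, all proteins in gene order, then the
        activated signaling species.
        """
        names = [f"{g.name}_mRNA" for g in self.genes]
        names += [f"{g.name}_protein" for g in self.genes]
        names += list(SIGNAL_SPECIES)
        return {n: i for i, n in enumerate(names)}

    @property
    def n_states(self) -> int:
        return 2 * len(self.genes) + len(SIGNAL_SPECIES)

    def regulators_of(self, target: str) -> list[RegulatoryInteraction]:
        return [e for e in self.interactions if e.target == target]

    def table_edges(self) -> list[RegulatoryInteraction]:
        """Edges of the curated integration/phenotype connectivity table."""
        return [e for e in self.interactions if e.source == "table"]

    # --- validation --------------------------------------------------------
    def validate(self) -> "NetworkModel":
        problems: list[str] = []
        seen: set[str] = set()
        for g in self.genes:
            if g.name in seen:
                problems.append(f"gene {g.name}: declared more than once")
            seen.add(g.name)
            problems.extend(g.validate())
        valid_effectors = seen | set(SIGNAL_SPECIES)
        for e in self.interactions:
            problems.extend(e.validate())
            if e.effector not in valid_effectors:
                problems.append(
                    f"edge {e.effector}->{e.target}: unknown effector {e.effector!r}")
            if e.target not in seen:
                problems.append(
                    f"edge {e.effector}->{e.target}: unknown target {e.target!r}")
        problems.extend(self.parameters.validate())
        if problems:
            raise NetworkValidationError(problems)
        return self

    def copy(self) -> "NetworkModel":
        return _copy.deepcopy(self)


# ---------------------------------------------------------------------------
# configuration I/O
# ---------------------------------------------------------------------------

def _model_from_mapping(doc: Mapping) -> NetworkModel:
    problems: list[str] = []
    params = GlobalParameters(**doc.get("parameters", {}))
    genes = []
    for entry in doc.get("genes", []):
        try:
            genes.append(GeneRecord(**entry))
        except TypeError as exc:
            problems.append(f"gene entry {entry.get('name', '?')}: {exc}")
    interactions = []
    for entry in doc.get("interactions", []):
        try:
            interactions.append(RegulatoryInteraction(**entry))
        except TypeError as exc:
            problems.append(
                f"edge entry {entry.get('effector', '?')}->{entry.get('target', '?')}: {exc}")
    if problems:
        raise NetworkValidationError(problems)
    return NetworkModel(genes=genes, interactions=interactions, parameters=params).validate()


def load_network(config_path: str | Path) -> NetworkModel:
    """Load and validate a network model from a YAML configuration file."""
    path = Path(config_path)
    with path.open() as fh:
        doc = yaml.safe_load(fh)
    if not isinstance(doc, Mapping):
        raise NetworkValidationError([f"{path}: configuration must be a mapping"])
    return _model_from_mapping(doc)


def default_network() -> NetworkModel:
    """The shipped ATRA differentiation network (curated connectivity table +
    initiation-layer feedback), with the canonical ground-truth parameters."""
    path = Path(__file__).parent / "data" / "network_default.yaml"
    return load_network(path)


def save_network(model: NetworkModel, path: str | Path) -> None:
    """Serialize a model back to YAML (round-trips with :func:`load_network`)."""
    doc = {
        "parameters": {k: getattr(model.parameters, k)
                       for k in GlobalParameters.__dataclass_fields__},
        "genes": [
            {k: getattr(g, k) for k in GeneRecord.__dataclass_fields__
             if getattr(g, k) is not None}
            for g in model.genes
        ],
        "interactions": [
            {k: getattr(e, k) for k in RegulatoryInteraction.__dataclass_fields__}
            for e in model.interactions
        ],
    }
    with Path(path).open("w") as fh:
        yaml.safe_dump(doc, fh, sort_keys=False)


# ---------------------------------------------------------------------------
# operations
# ---------------------------------------------------------------------------

def initiation_submodel(model: NetworkModel) -> NetworkModel:
    """The self-contained signal-initiation subsystem.

    Keeps the initiation-module genes and the promoter edges among them (the
    feedback closure plus the Trigger autoregulatory edge).  Valid because
    the initiation layer receives no input from downstream transcription
    factors, so its trajectories equal those of the full model; raises if
    the configuration wires a downstream protein into an initiation
    promoter.
    """
    keep = {g.name for g in model.genes if g.module == "initiation"}
    edges = []
    for e in model.interactions:
        if e.target not in keep:
            continue
        effector_gene = "Trigger" if e.effector == "Trigger_active" else e.effector
        if e.effector not in SIGNAL_SPECIES and e.effector not in keep:
            raise ValueError(
                f"initiation gene {e.target} is regulated by downstream "
                f"effector {e.effector}; the subsystem is not closed")
        if effector_gene not in keep and e.effector not in SIGNAL_SPECIES:
            raise ValueError(f"unresolvable effector {e.effector}")
        edges.append(e)
    out = NetworkModel(
        genes=[g for g in model.genes if g.name in keep],
        interactions=edges,
        parameters=model.parameters)
    return out.validate()


def count_state_equations(model: NetworkModel, module: str) -> int:
    """Number of differential state variables of ``module`` in full-ODE mode.

    Every gene contributes an mRNA and a protein balance; the initiation
    module additionally carries the activated signaling species (activated
    Trigger, signalsome, cRaf-pS621).
    """
    if module not in MODULES:
        raise ValueError(f"unknown module {module!r}; expected one of {MODULES}")
    n = 2 * sum(1 for g in model.genes if g.module == module)
    if module == "initiation" and model.genes:
        n += len(SIGNAL_SPECIES)
    return n


def apply_gene_knockout(model: NetworkModel, gene_names: Iterable[str]) -> NetworkModel:
    """Return a copy with ``gene_copies = 0`` for each named gene."""
    names = set(gene_names)
    unknown = names - set(model.gene_names)
    if unknown:
        raise KeyError(f"unknown gene(s) in knockout: {sorted(unknown)}")
    out = model.copy()
    out.genes = [replace(g, gene_copies=0.0) if g.name in names else g
                 for g in out.genes]
    return out


def apply_connection_knockout(
    model: NetworkModel,
    edges: Iterable[tuple],
) -> NetworkModel:
    """Return a copy with the matched promoter edges' weights set to zero.

    ``edges`` contains ``(effector, target)`` pairs or ``(effector, target,
    sign)`` triples (the sign disambiguates dual edges such as an effector
    that both activates and represses the same promoter).  Matched edges are
    retained in the roster so matrices keep a fixed shape.
    """
    specs = [tuple(e) for e in edges]
    out = model.copy()
    new_edges = list(out.interactions)
    for spec in specs:
        if len(spec) == 2:
            eff, tgt = spec
            sign = None
        else:
            eff, tgt, sign = spec
        hits = [i for i, e in enumerate(new_edges)
                if e.effector == eff and e.target == tgt
                and (sign is None or e.sign == sign)]
        if not hits:
            raise KeyError(f"no declared interaction matches {spec}")
        for i in hits:
            new_edges[i] = replace(new_edges[i], weight=0.0)
    out.interactions = new_edges
    return out


def copies_to_concentration(copies: float, params: GlobalParameters) -> float:
    """Convert copies/cell to nM using the cytoplasmic volume."""
    import numpy as np
    if np.any(np.asarray(copies) < 0):
        raise ValueError("copy number must be >= 0")
    return copies * params.nM_per_copy


def concentration_to_copies(conc_nM: float, params: GlobalParameters) -> float:
    """Convert nM to copies/cell (inverse of :func:`copies_to_concentration`)."""
    import numpy as np
    if np.any(np.asarray(conc_nM) < 0):
        raise ValueError("concentration must be >= 0")
    return conc_nM / params.nM_per_copy
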