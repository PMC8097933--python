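"""Per-patient drug-target actionability from qualified alterations.

The rule, per drug target t within its pathway topology:

    S = pathway-activating alterations in upstream_of[t] (on or upstream
        of the target), minus excepted genes
    D = pathway-activating alterations in downstream_of[t]

    verdict = actionable   if S is non-empty and D is empty
              impaired     if D is non-empty
              no_evidence  otherwise

"Pathway-activating alteration" means an activating alteration of an
oncogene or an inactivating alteration of a tumor suppressor; VUS never
contribute.  PARP has no downstream set: its actionability rests on
synthetic lethality with defective DNA repair, not on a linear cascade.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import yaml

from .classify import QualifiedAlteration, is_vus

__all__ = [
    "DRUG_TARGETS",
    "PathwaySpec",
    "ActionabilityCall",
    "PathwayConfigError",
    "load_pathways",
    "default_pathways",
    "assess_target",
    "assess_parp",
    "assess_patient",
]

PATHWAY_NAMES = (
    "DNA_REPAIR",
    "RTK",
    "PI3K_AKT_MTOR",
    "RAS_MAPK",
    "CELL_CYCLE",
    "HEDGEHOG",
)

# Canonical reporting order of the 14 drug targets.
DRUG_TARGETS = (
    "PARP",
    "EGFR",
    "ERBB2",
    "KDR",
    "IGF1R",
    "MET",
    "RET",
    "PIK3CA",
    "AKT1",
    "MTOR",
    "KRAS",
    "MEK1_2",
    "CDK4_6",
    "SMO",
)

RTK_TARGETS = ("EGFR", "ERBB2", "KDR", "IGF1R", "MET", "RET")

VERDICTS = ("actionable", "impaired", "no_evidence")


class PathwayConfigError(ValueError):
    """Topology file violates the structural invariants."""


@dataclass
class PathwaySpec:
    name: str
    genes: tuple[str, ...]
    drug_targets: tuple[str, ...]
    upstream_of: dict[str, frozenset[str]]
    downstream_of: dict[str, frozenset[str]]
    exceptions: frozenset[tuple[str, str]] = field(default_factory=frozenset)

    def validate(self) -> None:
        if self.name not in PATHWAY_NAMES:
            raise PathwayConfigError(f"unknown pathway name {self.name!r}")
        for t in self.drug_targets:
            overlap = self.upstream_of[t] & self.downstream_of[t]
            if overlap:
                raise PathwayConfigError(
                    f"{self.name}/{t}: upstream and downstream overlap on "
                    f"{sorted(overlap)}"
                )


@dataclass
class ActionabilityCall:
    patient_id: str
    drug_target: str
    verdict: str
    sensitizing: list[QualifiedAlteration] = field(default_factory=list)
    negating: list[QualifiedAlteration] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.verdict not in VERDICTS:
            raise ValueError(f"unknown verdict {self.verdict!r}")


def _as_tuple(x) -> tuple[str, ...]:
    return tuple(str(g).upper() for g in x)


def load_pathways(
    path: str | Path | None = None,
    rtk_sensitizes_downstream: bool = False,
) -> list[PathwaySpec]:
    """Load and validate a topology YAML; ``None`` loads the packaged default.

    ``rtk_sensitizes_downstream`` adds the RTK genes to the upstream sets of
    the PI3K/AKT/MTOR and RAS/MAPK targets, crediting receptor gains as
    sensitizing for the cascade below.  Off by default: receptor-level
    alterations are not treated as evidence for downstream-node inhibitors.
    """
    if path is None:
        with resources.as_file(
            resources.files("oncoact.data").joinpath("pathways.yaml")
        ) as p:
            raw = yaml.safe_load(p.read_text())
    else:
        raw = yaml.safe_load(Path(path).read_text())

    exceptions = frozenset(
        (str(e["target"]).upper(), str(e["gene"]).upper())
        for e in raw.get("exceptions", [])
    )
    if ("PIK3CA", "PTEN") not in exceptions:
        raise PathwayConfigError(
            "topology must carry the (PIK3CA, PTEN) exception"
        )

    specs: list[PathwaySpec] = []
    downstream_cascade = ("PIK3CA", "AKT1", "MTOR", "KRAS", "MEK1_2")
    for name, body in raw["pathways"].items():
        targets = tuple(body["targets"])
        upstream = {}
        downstream = {}
        for t, maps in body["targets"].items():
            up = set(_as_tuple(maps.get("upstream", ())))
            if rtk_sensitizes_downstream and t in downstream_cascade:
                up |= set(RTK_TARGETS)
            upstream[t] = frozenset(up)
            downstream[t] = frozenset(_as_tuple(maps.get("downstream", ())))
        spec = PathwaySpec(
            name=name,
            genes=_as_tuple(body["genes"]),
            drug_targets=targets,
            upstream_of=upstream,
            downstream_of=downstream,
            exceptions=exceptions,
        )
        spec.validate()
        specs.append(spec)

    seen_targets = [t for s in specs for t in s.drug_targets]
    if len(seen_targets) != len(set(seen_targets)):
        raise PathwayConfigError("a drug target appears in more than one pathway")
    # Every pathway gene must be reachable through some target map somewhere.
    covered = set()
    for s in specs:
        for t in s.drug_targets:
            covered |= s.upstream_of[t] | s.downstream_of[t]
    for s in specs:
        missing = set(s.genes) - covered
        if missing:
            raise PathwayConfigError(
                f"{s.name}: gene(s) {sorted(missing)} appear in no "
                "upstream/downstream map of any target"
            )
    return specs


_DEFAULT_CACHE: list[PathwaySpec] | None = None


def default_pathways() -> list[PathwaySpec]:
    global _DEFAULT_CACHE
    if _DEFAULT_CACHE is None:
        _DEFAULT_CACHE = load_pathways(None)
    return _DEFAULT_CACHE


def _pathway_activating(a: QualifiedAlteration) -> bool:
    # Qualification already encodes direction: activating is only assigned to
    # oncogenes, inactivating only to tumor suppressors; both activate the
    # pathway (or disable repair).
    return a.effect in ("activating", "inactivating")


def assess_target(
    target: str,
    alterations: list[QualifiedAlteration],
    spec: PathwaySpec,
) -> ActionabilityCall:
    """Evaluate one drug target for one patient's qualified alterations."""
    if target not in spec.drug_targets:
        raise PathwayConfigError(
            f"target {target!r} not in pathway {spec.name!r}"
        )
    excepted = {g for (t, g) in spec.exceptions if t == target}
    visible = [
        a
        for a in alterations
        if not is_vus(a) and _pathway_activating(a) and a.gene not in excepted
    ]
    sensitizing = [a for a in visible if a.gene in spec.upstream_of[target]]
    negating = [a for a in visible if a.gene in spec.downstream_of[target]]
    if negating:
        verdict = "impaired"
    elif sensitizing:
        verdict = "actionable"
    else:
        verdict = "no_evidence"
    patient_id = alterations[0].patient_id if alterations else ""
    return ActionabilityCall(
        patient_id=patient_id,
        drug_target=target,
        verdict=verdict,
        sensitizing=sensitizing,
        negating=negating,
    )


def assess_parp(
    alterations: list[QualifiedAlteration],
    spec: PathwaySpec,
) -> ActionabilityCall:
    """PARP-inhibitor actionability: any inactivated DNA-repair gene counts."""
    return assess_target("PARP", alterations, spec)


def assess_patient(
    alterations: list[QualifiedAlteration],
    all_specs: list[PathwaySpec] | None = None,
    patient_id: str | None = None,
) -> list[ActionabilityCall]:
    """One call per drug target (14 with the default topology), fixed order."""
    specs = all_specs if all_specs is not None else default_pathways()
    by_target = {t: s for s in specs for t in s.drug_targets}
    order = [t for t in DRUG_TARGETS if t in by_target] + [
        t for t in by_target if t not in DRUG_TARGETS
    ]
    calls = []
    for t in order:
        call = assess_target(t, alterations, by_target[t])
        if patient_id is not None:
            call.patient_id = patient_id
        calls.append(call)
    return calls
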