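"""Model descriptions, file formats, and test-fixture generators.

The intracellular signaling network is not hard-coded: it is loaded from a
*model description* that lists species, parameters, and reactions with one
of three rate-law kinds (``mass_action``, ``hill_activation``,
``hill_repression``).  The native on-disk format is a small versioned YAML
schema; the same description can be written to and read from SBML Level 3
(species/parameters/reactions with the rate-law kind carried both in simple
MathML and in a package annotation that is authoritative on import).
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import yaml
from lxml import etree

SCHEMA = "angiosprout-model/1"
RATE_LAW_KINDS = ("mass_action", "hill_activation", "hill_repression")

_SBML_NS = "http://www.sbml.org/sbml/level3/version2/core"
_MATHML_NS = "http://www.w3.org/1998/Math/MathML"
_ANNOT_NS = "https://angiosprout.dev/ratelaw"


class ModelFormatError(ValueError):
    """Raised when a model description is malformed or uses unknown rate laws."""


@dataclass(frozen=True)
class SpeciesDef:
    id: str
    initial: float = 0.0
    boundary: bool = False


@dataclass(frozen=True)
class HillTerm:
    """One multiplicative Hill factor: modifier species (summed), fold a, midpoint m0."""

    modifier: tuple[str, ...]
    a: str
    m0: str


@dataclass(frozen=True)
class ReactionDef:
    id: str
    kind: str
    # mass action
    k: str | None = None
    rate_species: tuple[str, ...] = ()
    consume: tuple[str, ...] = ()
    produce: tuple[str, ...] = ()
    # hill
    product: str | None = None
    vmax: str | None = None
    h: str | None = None
    terms: tuple[HillTerm, ...] = ()


@dataclass
class ModelDescription:
    """Validated roster of species, parameters, and reactions."""

    name: str
    species: list[SpeciesDef]
    parameters: dict[str, float]
    reactions: list[ReactionDef]

    def __post_init__(self) -> None:
        self.validate()

    # -- introspection ---------------------------------------------------
    @property
    def species_ids(self) -> list[str]:
        return [s.id for s in self.species]

    @property
    def dynamic_species(self) -> list[SpeciesDef]:
        return [s for s in self.species if not s.boundary]

    def species_def(self, sid: str) -> SpeciesDef:
        for s in self.species:
            if s.id == sid:
                return s
        raise KeyError(sid)

    # -- validation ------------------------------------------------------
    def validate(self) -> None:
        if not self.species:
            raise ModelFormatError("model declares no species")
        ids = self.species_ids
        if len(set(ids)) != len(ids):
            raise ModelFormatError("duplicate species ids")
        known = set(ids)
        for name, value in self.parameters.items():
            if not np.isfinite(value) or value < 0:
                raise ModelFormatError(f"parameter {name!r} must be finite and >= 0")
        for r in self.reactions:
            if r.kind not in RATE_LAW_KINDS:
                raise ModelFormatError(f"reaction {r.id!r}: unknown rate-law kind {r.kind!r}")
            if r.kind == "mass_action":
                if r.k not in self.parameters:
                    raise ModelFormatError(f"reaction {r.id!r}: unknown rate constant {r.k!r}")
                refs = set(r.rate_species) | set(r.consume) | set(r.produce)
            else:
                if r.product not in known:
                    raise ModelFormatError(f"reaction {r.id!r}: unknown product {r.product!r}")
                for p in (r.vmax, r.h):
                    if p not in self.parameters:
                        raise ModelFormatError(f"reaction {r.id!r}: unknown parameter {p!r}")
                for t in r.terms:
                    for p in (t.a, t.m0):
                        if p not in self.parameters:
                            raise ModelFormatError(f"reaction {r.id!r}: unknown parameter {p!r}")
                refs = {m for t in r.terms for m in t.modifier}
            missing = refs - known
            if missing:
                raise ModelFormatError(f"reaction {r.id!r}: unknown species {sorted(missing)}")


# ---------------------------------------------------------------------------
# native YAML format
# ---------------------------------------------------------------------------

def _reaction_from_mapping(d: dict) -> ReactionDef:
    kind = d.get("kind")
    if kind == "mass_action":
        return ReactionDef(
            id=d["id"],
            kind=kind,
            k=d["k"],
            rate_species=tuple(d.get("rate_species", ())),
            consume=tuple(d.get("consume", ())),
            produce=tuple(d.get("produce", ())),
        )
    if kind in ("hill_activation", "hill_repression"):
        terms = tuple(
            HillTerm(modifier=tuple(t["modifier"]), a=t["a"], m0=t["m0"])
            for t in d.get("terms", ())
        )
        return ReactionDef(
            id=d["id"], kind=kind, product=d["product"], vmax=d["vmax"],
            h=d["h"], terms=terms,
        )
    raise ModelFormatError(f"reaction {d.get('id')!r}: unknown rate-law kind {kind!r}")


def _reaction_to_mapping(r: ReactionDef) -> dict:
    if r.kind == "mass_action":
        return {
            "id": r.id, "kind": r.kind, "k": r.k,
            "rate_species": list(r.rate_species),
            "consume": list(r.consume), "produce": list(r.produce),
        }
    return {
        "id": r.id, "kind": r.kind, "product": r.product, "vmax": r.vmax,
        "h": r.h,
        "terms": [{"modifier": list(t.modifier), "a": t.a, "m0": t.m0} for t in r.terms],
    }


def load_model(path: str | Path) -> ModelDescription:
    """Load a model description from native YAML or SBML (by extension)."""
    path = Path(path)
    if path.suffix.lower() in (".xml", ".sbml"):
        return read_sbml(path)
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    if not isinstance(doc, dict) or doc.get("schema") != SCHEMA:
        raise ModelFormatError(f"{path}: not a {SCHEMA} document")
    species = [
        SpeciesDef(id=s["id"], initial=float(s.get("initial", 0.0)),
                   boundary=bool(s.get("boundary", False)))
        for s in doc.get("species", ())
    ]
    parameters = {k: float(v) for k, v in (doc.get("parameters") or {}).items()}
    reactions = [_reaction_from_mapping(r) for r in doc.get("reactions", ())]
    return ModelDescription(doc.get("name", path.stem), species, parameters, reactions)


def save_model(model: ModelDescription, path: str | Path) -> None:
    """Write a model description to native YAML or SBML (by extension)."""
    path = Path(path)
    if path.suffix.lower() in (".xml", ".sbml"):
        write_sbml(model, path)
        return
    doc = {
        "schema": SCHEMA,
        "name": model.name,
        "species": [
            {"id": s.id, "initial": s.initial, **({"boundary": True} if s.boundary else {})}
            for s in model.species
        ],
        "parameters": dict(model.parameters),
        "reactions": [_reaction_to_mapping(r) for r in model.reactions],
    }
    with open(path, "w") as fh:
        yaml.safe_dump(doc, fh, sort_keys=False)


def packaged_model() -> ModelDescription:
    """The calibrated endothelial-cell signaling model shipped with the package."""
    ref = importlib.resources.files("angiosprout") / "models" / "intracellular.yaml"
    with importlib.resources.as_file(ref) as path:
        return load_model(path)


# ---------------------------------------------------------------------------
# SBML Level 3
# ---------------------------------------------------------------------------

def _mathml_times(parent: etree._Element, factors: list[str]) -> None:
    math = etree.SubElement(parent, f"{{{_MATHML_NS}}}math")
    if len(factors) == 1:
        ci = etree.SubElement(math, f"{{{_MATHML_NS}}}ci")
        ci.text = f" {factors[0]} "
        return
    apply = etree.SubElement(math, f"{{{_MATHML_NS}}}apply")
    etree.SubElement(apply, f"{{{_MATHML_NS}}}times")
    for f in factors:
        ci = etree.SubElement(apply, f"{{{_MATHML_NS}}}ci")
        ci.text = f" {f} "


def write_sbml(model: ModelDescription, path: str | Path) -> None:
    nsmap = {None: _SBML_NS, "asp": _ANNOT_NS}
    sbml = etree.Element(f"{{{_SBML_NS}}}sbml", nsmap=nsmap, level="3", version="2")
    m = etree.SubElement(sbml, f"{{{_SBML_NS}}}model", id=model.name)
    comp_list = etree.SubElement(m, f"{{{_SBML_NS}}}listOfCompartments")
    etree.SubElement(comp_list, f"{{{_SBML_NS}}}compartment", id="cell",
                     constant="true", spatialDimensions="3", size="1")
    sp_list = etree.SubElement(m, f"{{{_SBML_NS}}}listOfSpecies")
    for s in model.species:
        etree.SubElement(
            sp_list, f"{{{_SBML_NS}}}species", id=s.id, compartment="cell",
            initialAmount=repr(float(s.initial)),
            boundaryCondition="true" if s.boundary else "false",
            hasOnlySubstanceUnits="true", constant="false",
        )
    par_list = etree.SubElement(m, f"{{{_SBML_NS}}}listOfParameters")
    for name, value in model.parameters.items():
        etree.SubElement(par_list, f"{{{_SBML_NS}}}parameter", id=name,
                         value=repr(float(value)), constant="true")
    rx_list = etree.SubElement(m, f"{{{_SBML_NS}}}listOfReactions")
    for r in model.reactions:
        rx = etree.SubElement(rx_list, f"{{{_SBML_NS}}}reaction", id=r.id, reversible="false")
        annot = etree.SubElement(rx, f"{{{_SBML_NS}}}annotation")
        law = etree.SubElement(annot, f"{{{_ANNOT_NS}}}rateLaw", kind=r.kind)
        if r.kind == "mass_action":
            law.set("k", r.k)
            law.set("rateSpecies", " ".join(r.rate_species))
            reactants, products = r.consume, r.produce
        else:
            law.set("vmax", r.vmax)
            law.set("h", r.h)
            for t in r.terms:
                etree.SubElement(law, f"{{{_ANNOT_NS}}}hillTerm",
                                 modifier=" ".join(t.modifier), a=t.a, m0=t.m0)
            reactants, products = (), (r.product,)
        if reactants:
            lst = etree.SubElement(rx, f"{{{_SBML_NS}}}listOfReactants")
            for sid in reactants:
                etree.SubElement(lst, f"{{{_SBML_NS}}}speciesReference",
                                 species=sid, stoichiometry="1", constant="true")
        if products:
            lst = etree.SubElement(rx, f"{{{_SBML_NS}}}listOfProducts")
            for sid in products:
                etree.SubElement(lst, f"{{{_SBML_NS}}}speciesReference",
                                 species=sid, stoichiometry="1", constant="true")
        kl = etree.SubElement(rx, f"{{{_SBML_NS}}}kineticLaw")
        if r.kind == "mass_action":
            _mathml_times(kl, [r.k, *r.rate_species])
        else:
            _mathml_times(kl, [r.vmax])  # Hill law authoritative form is in the annotation
    tree = etree.ElementTree(sbml)
    tree.write(str(path), xml_declaration=True, encoding="UTF-8", pretty_print=True)


def read_sbml(path: str | Path) -> ModelDescription:
    tree = etree.parse(str(path))
    root = tree.getroot()
    m = root.find(f"{{{_SBML_NS}}}model")
    if m is None:
        raise ModelFormatError(f"{path}: no <model> element")
    species = [
        SpeciesDef(
            id=el.get("id"),
            initial=float(el.get("initialAmount", "0")),
            boundary=el.get("boundaryCondition", "false") == "true",
        )
        for el in m.findall(f"{{{_SBML_NS}}}listOfSpecies/{{{_SBML_NS}}}species")
    ]
    parameters = {
        el.get("id"): float(el.get("value", "0"))
        for el in m.findall(f"{{{_SBML_NS}}}listOfParameters/{{{_SBML_NS}}}parameter")
    }
    reactions = []
    for rx in m.findall(f"{{{_SBML_NS}}}listOfReactions/{{{_SBML_NS}}}reaction"):
        law = rx.find(f"{{{_SBML_NS}}}annotation/{{{_ANNOT_NS}}}rateLaw")
        if law is None:
            raise ModelFormatError(
                f"reaction {rx.get('id')!r}: no rate-law annotation; refusing to guess"
            )
        kind = law.get("kind")
        if kind not in RATE_LAW_KINDS:
            raise ModelFormatError(f"reaction {rx.get('id')!r}: unknown rate-law kind {kind!r}")
        consume = [
            el.get("species")
            for el in rx.findall(f"{{{_SBML_NS}}}listOfReactants/{{{_SBML_NS}}}speciesReference")
        ]
        produce = [
            el.get("species")
            for el in rx.findall(f"{{{_SBML_NS}}}listOfProducts/{{{_SBML_NS}}}speciesReference")
        ]
        if kind == "mass_action":
            reactions.append(ReactionDef(
                id=rx.get("id"), kind=kind, k=law.get("k"),
                rate_species=tuple((law.get("rateSpecies") or "").split()),
                consume=tuple(consume), produce=tuple(produce),
            ))
        else:
            terms = tuple(
                HillTerm(modifier=tuple(t.get("modifier").split()), a=t.get("a"), m0=t.get("m0"))
                for t in law.findall(f"{{{_ANNOT_NS}}}hillTerm")
            )
            reactions.append(ReactionDef(
                id=rx.get("id"), kind=kind, product=produce[0], vmax=law.get("vmax"),
                h=law.get("h"), terms=terms,
            ))
    return ModelDescription(m.get("id", Path(path).stem), species, parameters, reactions)


# ---------------------------------------------------------------------------
# fixture generators
# ---------------------------------------------------------------------------

def make_fixture(kind: str, params: dict | None = None, seed: int = 0):
    """Deterministic test fixtures.

    ``two_cell`` / ``ring_n``: a static ring of coupled signaling cells (see
    :class:`angiosprout.signaling.RingSystem`); ``vessel_mask``: a binary
    vessel mask with a known junction count for the branching analysis.
    """
    params = dict(params or {})
    if kind == "two_cell":
        return make_fixture("ring_n", {**params, "n": 2}, seed)
    if kind == "ring_n":
        from .signaling import RingSystem, SignalingModel

        model = params.pop("model", None) or SignalingModel(packaged_model())
        n = int(params.pop("n", 4))
        return RingSystem(model, n=n, seed=seed, **params)
    if kind == "vessel_mask":
        return vessel_mask(
            n_junctions=int(params.pop("n_junctions", 3)),
            size=int(params.pop("size", 64)),
            seed=seed,
        )
    raise ValueError(f"unknown fixture kind {kind!r}")


def vessel_mask(n_junctions: int = 3, size: int = 64, seed: int = 0) -> np.ndarray:
    """Binary mask of a 1-pixel backbone with ``n_junctions`` T-spurs.

    The spur feet are spaced at least 4 pixels apart along the backbone so
    each junction forms its own cluster after skeletonization.
    """
    rng = np.random.default_rng(seed)
    mask = np.zeros((size, size), dtype=bool)
    row = size // 2
    mask[row, 2:size - 2] = True
    candidates = np.arange(6, size - 6)
    feet: list[int] = []
    while len(feet) < n_junctions:
        c = int(rng.choice(candidates))
        if all(abs(c - f) >= 4 for f in feet):
            feet.append(c)
    for i, c in enumerate(sorted(feet)):
        spur = 5 + int(rng.integers(0, 4))
        if i % 2 == 0:
            mask[row - spur:row, c] = True
        else:
            mask[row + 1:row + 1 + spur, c] = True
    return mask


# ---------------------------------------------------------------------------
# snapshot / mask input-output
# ---------------------------------------------------------------------------

def write_mask_png(mask: np.ndarray, path: str | Path) -> None:
    """Write a binary occupancy mask as an 8-bit grayscale PNG."""
    import imageio.v3 as iio

    iio.imwrite(str(path), (np.asarray(mask, bool) * np.uint8(255)))


def read_mask(path: str | Path) -> np.ndarray:
    """Read a binary mask from PNG (any nonzero pixel) or CSV."""
    path = Path(path)
    if path.suffix.lower() == ".csv":
        return np.loadtxt(path, delimiter=",") > 0
    import imageio.v3 as iio

    img = iio.imread(str(path))
    if img.ndim == 3:
        img = img[..., :3].max(axis=-1)
    return np.asarray(img) > 0


def write_field_csv(grid: np.ndarray, path: str | Path) -> None:
    np.savetxt(path, np.asarray(grid, float), delimiter=",", fmt="%.6g")


def write_record(record, outdir: str | Path) -> None:
    """Write one simulation record: per-time occupancy PNG/CSV, the tip/agent
    time series as CSV, the final agent table when present, and a manifest."""
    import json

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    for t, occ in zip(record.snapshot_times, record.occupancy):
        stem = f"occupancy_t{t:07.2f}h"
        write_mask_png(occ, outdir / f"{stem}.png")
        np.savetxt(outdir / f"{stem}.csv", occ.astype(np.uint8), delimiter=",", fmt="%d")
    import pandas as pd

    pd.DataFrame({
        "time_h": record.step_times,
        "tip_count": record.step_tip_counts,
        "agent_count": record.step_agent_counts,
    }).to_csv(outdir / "timeseries.csv", index=False)
    if record.agent_table is not None:
        record.agent_table.to_csv(outdir / "agents.csv", index=False)
    manifest = {
        "grid_shape": list(record.grid_shape),
        "dx_um": record.dx_um,
        "seed": record.seed,
        "scenario": record.scenario,
        "snapshot_times_h": list(record.snapshot_times),
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2))
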