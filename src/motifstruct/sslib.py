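"""Registry of canonical secondary-structure categories and their templates.

The classifier recognises 31 named secondary-structure categories — six
helix types, two strand types, eight α-turn subtypes, nine β-turn types,
three γ-turn types, three π-turn subtypes — plus *random coil*, the
fallback for instances matching none of them within its variation limit.
A δ-turn category is registered but permanently unavailable: no structural
example of it exists, so nothing can ever be assigned to it.

Each available category carries a canonical template (a coordinate segment
under the active atom selection) and a *variation limit*: the maximum
pairwise centroid score among its known examples, i.e. the acceptance
radius for assignment.  Templates come either from registered exemplar
segments (e.g. extracted from real structures) or from ideal φ/ψ dihedral
recipes; the recipe values are literature constants kept in an editable
registry, so a user can reproduce any preferred convention.

Because the centroid score requires equal atom counts, templates are
always realised at the query window's length (and glycine layout); recipes
make this exact, exemplar templates are trimmed.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field

import numpy as np
import yaml

from ._geometry import backbone_dihedrals, build_backbone
from .centroid import (
    DEFAULT_WEIGHTS,
    WeightScheme,
    centroid_score,
    pairwise_max_score,
)
from .errors import LibraryError
from .structure_io import DEFAULT_SELECTION, SegmentCoordinates

logger = logging.getLogger(__name__)

RANDOM_COIL = "random coil"

#: Registry order — also the tie-break order during assignment.
SS_CATEGORIES = (
    "alpha-helix", "pi-helix", "2-7 helix", "3-10 helix",
    "polyproline helix", "collagen helix",
    "beta-strand", "beta-bulge",
    "alpha-turn I-aRS", "alpha-turn I-aLS", "alpha-turn II-aRS",
    "alpha-turn II-aLS", "alpha-turn I-aRU", "alpha-turn I-aLU",
    "alpha-turn II-aLU", "alpha-turn I-aC",
    "beta-turn I", "beta-turn II", "beta-turn VIII", "beta-turn I'",
    "beta-turn II'", "beta-turn VIa1", "beta-turn VIa2", "beta-turn VIb",
    "beta-turn IV",
    "gamma-turn I", "gamma-turn II", "gamma-turn III",
    "pi-turn HB", "pi-turn NHB", "pi-turn SCH",
    "delta-turn",        # named but no example exists: never assignable
    RANDOM_COIL,
)

DSSP_LETTERS = {
    "alpha-helix": "H", "pi-helix": "I", "3-10 helix": "G",
    "beta-strand": "E", "beta-bulge": "E", RANDOM_COIL: "C",
}


@dataclass(frozen=True)
class SSType:
    name: str
    dssp_letter: str | None = None

    def __post_init__(self):
        if self.name not in SS_CATEGORIES:
            raise LibraryError(f"unknown secondary-structure category "
                               f"{self.name!r}")


def _check_angle(a: float) -> float:
    if not (-180.0 < a <= 180.0):
        raise ValueError(f"dihedral {a} outside (-180, 180]")
    return float(a)


@dataclass(frozen=True)
class DihedralRecipe:
    """Per-residue (φ, ψ) in degrees defining an ideal conformation.

    ``periodic`` recipes (helices, strands) tile their core to any length;
    aperiodic recipes (turns) keep the core central and pad both sides
    with the ``flank`` conformation (extended strand by default).
    ω is fixed at 180° (trans) unless overridden.
    """

    core: tuple  # ((phi, psi), ...)
    periodic: bool = True
    flank: tuple = (-120.0, 120.0)
    omega: float = 180.0

    def __post_init__(self):
        for phi, psi in self.core:
            _check_angle(phi), _check_angle(psi)
        _check_angle(self.flank[0]), _check_angle(self.flank[1])

    def expand(self, n_residues: int) -> list:
        """The (φ, ψ) list for a chain of *n_residues*."""
        if n_residues < 2:
            raise ValueError("need at least 2 residues")
        if self.periodic:
            reps = itertools.cycle(self.core)
            return [next(reps) for _ in range(n_residues)]
        if n_residues <= len(self.core):
            start = (len(self.core) - n_residues) // 2
            return list(self.core[start : start + n_residues])
        pad = n_residues - len(self.core)
        before = pad // 2
        after = pad - before
        return ([self.flank] * before + list(self.core)
                + [self.flank] * after)


# Ideal (φ, ψ) values: helix/strand/polyproline/γ-turn values are textbook
# constants; turn subtypes follow the standard Hutchinson–Thornton (β) and
# Pavone (α) classifications at representative central-residue angles.
# All editable — load_recipes() reads a YAML override.
DEFAULT_RECIPES: dict = {
    "alpha-helix":       DihedralRecipe((( -57.0,  -47.0),)),
    "pi-helix":          DihedralRecipe((( -57.0,  -70.0),)),
    "2-7 helix":         DihedralRecipe((( -65.0,  -40.0),)),
    "3-10 helix":        DihedralRecipe((( -49.0,  -26.0),)),
    "polyproline helix": DihedralRecipe((( -75.0,  145.0),)),
    "collagen helix":    DihedralRecipe((( -72.0,  158.0),)),
    "beta-strand":       DihedralRecipe(((-120.0,  120.0),)),
    "beta-bulge":        DihedralRecipe(((-105.0,  115.0), (-60.0, -35.0)),
                                        periodic=False),
    "alpha-turn I-aRS":  DihedralRecipe((( -60.0,  -29.0), (-72.0, -29.0),
                                         ( -96.0,  -20.0)), periodic=False),
    "alpha-turn I-aLS":  DihedralRecipe(((  48.0,   42.0), ( 67.0,  33.0),
                                         (  70.0,   32.0)), periodic=False),
    "alpha-turn II-aRS": DihedralRecipe((( -59.0,  129.0), ( 88.0, -16.0),
                                         ( -91.0,  -32.0)), periodic=False),
    "alpha-turn II-aLS": DihedralRecipe(((  53.0, -137.0), (-95.0,  81.0),
                                         (  57.0,   38.0)), periodic=False),
    "alpha-turn I-aRU":  DihedralRecipe((( -61.0,  158.0), ( 64.0,  37.0),
                                         (  62.0,   39.0)), periodic=False),
    "alpha-turn I-aLU":  DihedralRecipe(((  65.0, -160.0), (-62.0, -39.0),
                                         ( -68.0,  -39.0)), periodic=False),
    "alpha-turn II-aLU": DihedralRecipe(((  61.0, -115.0), (-82.0,  -5.0),
                                         (  64.0,   35.0)), periodic=False),
    "alpha-turn I-aC":   DihedralRecipe(((-103.0,  143.0), (-85.0,   2.0),
                                         ( -54.0,  -42.0)), periodic=False),
    "beta-turn I":       DihedralRecipe((( -60.0,  -30.0), (-90.0,   0.0)),
                                        periodic=False),
    "beta-turn II":      DihedralRecipe((( -60.0,  120.0), ( 80.0,   0.0)),
                                        periodic=False),
    "beta-turn VIII":    DihedralRecipe((( -60.0,  -30.0), (-120.0, 120.0)),
                                        periodic=False),
    "beta-turn I'":      DihedralRecipe(((  60.0,   30.0), ( 90.0,   0.0)),
                                        periodic=False),
    "beta-turn II'":     DihedralRecipe(((  60.0, -120.0), (-80.0,   0.0)),
                                        periodic=False),
    "beta-turn VIa1":    DihedralRecipe((( -60.0,  120.0), (-90.0,   0.0)),
                                        periodic=False),
    "beta-turn VIa2":    DihedralRecipe(((-120.0,  120.0), (-60.0,   0.0)),
                                        periodic=False),
    "beta-turn VIb":     DihedralRecipe(((-135.0,  135.0), (-75.0,  160.0)),
                                        periodic=False),
    "beta-turn IV":      DihedralRecipe((( -61.0,   10.0), (-53.0,   17.0)),
                                        periodic=False),
    "gamma-turn I":      DihedralRecipe(((  75.0,  -64.0),), periodic=False),
    "gamma-turn II":     DihedralRecipe((( -79.0,   69.0),), periodic=False),
    "gamma-turn III":    DihedralRecipe(((  85.0,  -50.0),), periodic=False),
    "pi-turn HB":        DihedralRecipe((( -60.0,  -30.0), (-60.0, -30.0),
                                         ( -90.0,    0.0), (-90.0,   0.0)),
                                        periodic=False),
    "pi-turn NHB":       DihedralRecipe((( -65.0,  -40.0), (-65.0, -40.0),
                                         (-100.0,   10.0), ( 60.0,  40.0)),
                                        periodic=False),
    "pi-turn SCH":       DihedralRecipe((( -55.0,  -45.0), (-75.0, -20.0),
                                         ( -95.0,   15.0), (-80.0, -15.0)),
                                        periodic=False),
    # "delta-turn": no example exists in the literature -> no recipe.
}


def load_recipes(path) -> dict:
    """Merge a YAML recipe override into the defaults.

    YAML schema per category::

        alpha-helix:
          core: [[-57, -47]]
          periodic: true
          flank: [-120, 120]   # optional
    """
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    recipes = dict(DEFAULT_RECIPES)
    for name, entry in raw.items():
        if name not in SS_CATEGORIES:
            raise LibraryError(f"unknown category {name!r} in recipe file")
        recipes[name] = DihedralRecipe(
            core=tuple(tuple(map(float, pair)) for pair in entry["core"]),
            periodic=bool(entry.get("periodic", True)),
            flank=tuple(map(float, entry.get("flank", (-120.0, 120.0)))),
            omega=float(entry.get("omega", 180.0)),
        )
    return recipes


def build_ideal_backbone(recipe: DihedralRecipe, n_residues: int,
                         sequence: str | None = None,
                         name: str = "ideal") -> SegmentCoordinates:
    """Construct an ideal N/CA/C/CB segment from a dihedral recipe.

    *sequence* (optional, length ``n_residues``) controls glycine
    positions (no CB) and the recorded residue sequence; default is
    poly-alanine.  Deterministic.
    """
    if n_residues < 2:
        raise ValueError("need at least 2 residues to define a dihedral")
    if sequence is None:
        sequence = "A" * n_residues
    if len(sequence) != n_residues:
        raise ValueError("sequence length must equal n_residues")
    gly = tuple(i for i, aa in enumerate(sequence) if aa == "G")
    phi_psi = recipe.expand(n_residues)
    coords, _layout = build_backbone(phi_psi, omega=recipe.omega,
                                     gly_positions=gly)
    return SegmentCoordinates(
        source=(name, "A", 1, n_residues),
        atom_selection=DEFAULT_SELECTION,
        coordinates=coords,
        residue_sequence=sequence,
        exceptions=gly,
    )


def measure_recipe_dihedrals(segment: SegmentCoordinates) -> list:
    """Re-measure per-residue (φ, ψ) from a built N/CA/C(/CB) segment."""
    n_res = segment.n_residues
    N, CA, C = [], [], []
    i = 0
    for ridx in range(n_res):
        N.append(segment.coordinates[i])
        CA.append(segment.coordinates[i + 1])
        C.append(segment.coordinates[i + 2])
        i += 3 if ridx in segment.exceptions else 4
    return backbone_dihedrals(np.array(N), np.array(CA), np.array(C))


@dataclass
class SSEntry:
    ss_type: str
    variation_limit: float
    provenance: str                       # "recipe" | "exemplar"
    recipe: DihedralRecipe | None = None
    exemplar: SegmentCoordinates | None = None
    exemplars: list = field(default_factory=list)

    @property
    def available(self) -> bool:
        return self.recipe is not None or self.exemplar is not None


@dataclass
class SSLibrary:
    """Canonical template + variation limit per available category."""

    entries: dict            # name -> SSEntry, registry order
    weights: WeightScheme = DEFAULT_WEIGHTS
    normalize: bool = True
    floor: float = 0.05

    @property
    def available_types(self) -> list:
        return [name for name, e in self.entries.items() if e.available]

    def variation_limit(self, ss_type: str) -> float:
        return self.entries[ss_type].variation_limit

    def canonical_of(self, ss_type: str, n_residues: int,
                     gly_positions: tuple = ()) -> SegmentCoordinates:
        """The canonical template realised at the query window length.

        Random coil has no template by construction (it is the fallback,
        not a shape); requesting it is an error.
        """
        if ss_type == RANDOM_COIL:
            raise LibraryError("random coil is the fallback category and "
                               "has no canonical template")
        if ss_type not in self.entries or not self.entries[ss_type].available:
            raise LibraryError(f"category {ss_type!r} is not available in "
                               "this library")
        entry = self.entries[ss_type]
        if entry.provenance == "recipe":
            seq = "".join("G" if i in set(gly_positions) else "A"
                          for i in range(n_residues))
            return build_ideal_backbone(entry.recipe, n_residues,
                                        sequence=seq, name=ss_type)
        seg = entry.exemplar
        if n_residues > seg.n_residues:
            raise LibraryError(
                f"window of {n_residues} residues exceeds the "
                f"{seg.n_residues}-residue exemplar template for {ss_type}")
        return _trim_segment(seg, n_residues, tuple(gly_positions))


def _trim_segment(seg: SegmentCoordinates, n_residues: int,
                  gly_positions: tuple) -> SegmentCoordinates:
    """Central n_residues window of an exemplar, with CB dropped at the
    requested glycine positions."""
    start = (seg.n_residues - n_residues) // 2
    rows, new_exc = [], []
    i = 0
    per_res = len(seg.atom_selection)
    for ridx in range(seg.n_residues):
        names = [a for a in seg.atom_selection
                 if not (a == "CB" and ridx in seg.exceptions)]
        if start <= ridx < start + n_residues:
            out_idx = ridx - start
            for k, a in enumerate(names):
                if a == "CB" and out_idx in gly_positions:
                    continue
                rows.append(i + k)
            if "CB" not in names or out_idx in gly_positions:
                new_exc.append(out_idx)
        i += len(names)
    return SegmentCoordinates(
        source=seg.source,
        atom_selection=seg.atom_selection,
        coordinates=seg.coordinates[rows],
        residue_sequence=seg.residue_sequence[start : start + n_residues],
        exceptions=tuple(new_exc),
    )


def library_from_recipes(recipes: dict | None = None,
                         weights: WeightScheme = DEFAULT_WEIGHTS,
                         normalize: bool = True,
                         floor: float = 0.05) -> SSLibrary:
    """Library with recipe-derived canonicals and floor variation limits.

    With no registered examples there is no observed variability, so every
    limit is the configured floor.
    """
    recipes = recipes if recipes is not None else DEFAULT_RECIPES
    entries = {}
    for name in SS_CATEGORIES:
        if name == RANDOM_COIL:
            continue
        recipe = recipes.get(name)
        if recipe is None:
            logger.info("category %s has no recipe/examples; unavailable",
                        name)
            entries[name] = SSEntry(name, 0.0, "recipe", recipe=None)
        else:
            entries[name] = SSEntry(name, floor, "recipe", recipe=recipe)
    return SSLibrary(entries=entries, weights=weights, normalize=normalize,
                     floor=floor)


def compute_variation_limits(examples: dict,
                             weights: WeightScheme = DEFAULT_WEIGHTS,
                             normalize: bool = True,
                             floor: float = 0.05,
                             representative: str = "medoid") -> SSLibrary:
    """Build a library from registered example segments per category.

    Per category: variation limit = max pairwise centroid score among its
    examples (never below *floor*; a single-example category gets exactly
    the floor); canonical template = the designated representative —
    ``"medoid"`` (minimum summed score to the others; default) or
    ``"first"`` (first registered).  Categories with zero examples are
    marked unavailable and logged.  Deterministic given the registry.
    """
    if representative not in ("medoid", "first"):
        raise ValueError("representative must be 'medoid' or 'first'")
    entries = {}
    for name in SS_CATEGORIES:
        if name == RANDOM_COIL:
            continue
        segs = list(examples.get(name, ()))
        if not segs:
            logger.info("no examples registered for %s; marked unavailable",
                        name)
            entries[name] = SSEntry(name, 0.0, "exemplar", exemplar=None)
            continue
        if len(segs) == 1:
            limit = floor
            rep = segs[0]
        else:
            limit = max(pairwise_max_score(segs, weights, normalize), floor)
            if representative == "first":
                rep = segs[0]
            else:
                sums = [
                    sum(centroid_score(s, t, weights, normalize).value
                        for t in segs if t is not s)
                    for s in segs
                ]
                rep = segs[int(np.argmin(sums))]
        entries[name] = SSEntry(name, limit, "exemplar", exemplar=rep,
                                exemplars=segs)
    return SSLibrary(entries=entries, weights=weights, normalize=normalize,
                     floor=floor)


def save_library(library: SSLibrary, directory) -> None:
    """Serialize a library to a YAML + PDB-fixture bundle."""
    from pathlib import Path

    from .structure_io import segment_to_model, write_pdb

    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    meta = {
        "weights": library.weights.kind,
        "normalize": library.normalize,
        "floor": library.floor,
        "entries": {},
    }
    for name, entry in library.entries.items():
        if not entry.available:
            continue
        rec: dict = {"variation_limit": float(entry.variation_limit),
                     "provenance": entry.provenance}
        if entry.provenance == "recipe":
            rec["core"] = [list(p) for p in entry.recipe.core]
            rec["periodic"] = entry.recipe.periodic
            rec["flank"] = list(entry.recipe.flank)
        else:
            fname = name.replace(" ", "_").replace("'", "p") + ".pdb"
            (directory / fname).write_text(
                write_pdb(segment_to_model(entry.exemplar, name)))
            rec["pdb"] = fname
            rec["sequence"] = entry.exemplar.residue_sequence
        meta["entries"][name] = rec
    (directory / "library.yaml").write_text(yaml.safe_dump(meta))


def load_library(directory) -> SSLibrary:
    from pathlib import Path

    from .structure_io import extract_segment, read_pdb

    directory = Path(directory)
    meta = yaml.safe_load((directory / "library.yaml").read_text())
    weights = WeightScheme(meta["weights"])
    entries = {}
    for name in SS_CATEGORIES:
        if name == RANDOM_COIL:
            continue
        rec = meta["entries"].get(name)
        if rec is None:
            entries[name] = SSEntry(name, 0.0, "recipe", recipe=None)
        elif rec["provenance"] == "recipe":
            entries[name] = SSEntry(
                name, float(rec["variation_limit"]), "recipe",
                recipe=DihedralRecipe(
                    core=tuple(tuple(p) for p in rec["core"]),
                    periodic=rec["periodic"],
                    flank=tuple(rec["flank"])))
        else:
            model = read_pdb((directory / rec["pdb"]).read_text(), name)
            chain = model.chains[0]
            nums = [r.number for r in model.residues(chain)]
            seg = extract_segment(model, chain, min(nums), max(nums))
            entries[name] = SSEntry(name, float(rec["variation_limit"]),
                                    "exemplar", exemplar=seg)
    return SSLibrary(entries=entries, weights=weights,
                     normalize=bool(meta["normalize"]),
                     floor=float(meta["floor"]))
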