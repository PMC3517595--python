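"""Seeded synthetic inputs for the whole pipeline at desk scale.

Emulated here: backbone+CB coordinate segments built from the canonical
φ/ψ recipe of each secondary-structure category with isotropic Gaussian
coordinate noise; decoy corpora with a stated category mixture; random
protein sequences with motifs planted at recorded positions; and binary
order/disorder tracks with stated structured/unstructured/hybrid window
proportions.  Every generator takes a seed and is byte-deterministic;
each emits a manifest that downstream recovery tests treat as the only
source of ground truth.

Random-coil fixtures are self-avoiding random dihedral walks (resampled on
CA clashes), not Gaussian point clouds, so they stay chemically plausible
chains that genuinely match no template.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import LibraryError
from .lexicon import AMINO_ACIDS, MotifPattern, lexicon_size
from .sslib import DEFAULT_RECIPES, RANDOM_COIL, build_ideal_backbone
from .structure_io import (
    DEFAULT_SELECTION,
    SegmentCoordinates,
    StructureModel,
    segment_to_model,
    write_pdb,
)


@dataclass
class CorpusSpec:
    """Study conditions for a synthetic corpus.

    mixture maps category name (incl. "random coil") to its fraction;
    fractions must sum to 1.  ``planting_rate`` is the fraction of
    structures whose sequence carries the motif at the recorded window.
    ``disorder_proportions`` = (p_structured, p_unstructured, p_hybrid).
    """

    seed: int
    n_structures: int
    mixture: dict
    noise_sd: float = 0.15
    pattern: MotifPattern | None = None
    planting_rate: float = 1.0
    length_range: tuple = (8, 16)
    disorder_proportions: tuple = (0.27, 0.28, 0.45)

    def __post_init__(self):
        total = sum(self.mixture.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"mixture fractions sum to {total}, not 1")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be nonnegative")
        if abs(sum(self.disorder_proportions) - 1.0) > 1e-9:
            raise ValueError("disorder proportions must sum to 1")


def _random_sequence(rng, length, avoid_pattern=None, max_tries=200):
    """Random sequence over the 20 canonical residues, optionally with no
    window matching *avoid_pattern*."""
    aas = np.array(list(AMINO_ACIDS))
    for _ in range(max_tries):
        seq = "".join(rng.choice(aas, size=length))
        if avoid_pattern is None:
            return seq
        from .lexicon import scan_sequence
        if not scan_sequence(seq, avoid_pattern):
            return seq
    raise RuntimeError("could not draw a pattern-free sequence")


def _draw_lexicon(rng, pattern: MotifPattern) -> str:
    return "".join(rng.choice(sorted(pos)) for pos in pattern.positions)


def _coil_backbone(rng, n_residues: int, sequence: str,
                   max_tries: int = 50) -> SegmentCoordinates:
    """Self-avoiding random dihedral walk (non-glycine Ramachandran-wide
    draws, resampled when CA atoms clash below 3.5 Å)."""
    from ._geometry import build_backbone

    gly = tuple(i for i, aa in enumerate(sequence) if aa == "G")
    for _ in range(max_tries):
        phi = rng.uniform(-180.0, 180.0, n_residues)
        psi = rng.uniform(-180.0, 180.0, n_residues)
        coords, layout = build_backbone(list(zip(phi, psi)),
                                        gly_positions=gly)
        ca = np.array([coords[i] for i, (_, name) in enumerate(layout)
                       if name == "CA"])
        d = np.linalg.norm(ca[:, None] - ca[None, :], axis=-1)
        iu = np.triu_indices(n_residues, k=2)
        if len(iu[0]) == 0 or d[iu].min() > 3.5:
            return SegmentCoordinates(
                source=("coil", "A", 1, n_residues),
                atom_selection=DEFAULT_SELECTION,
                coordinates=coords, residue_sequence=sequence,
                exceptions=gly)
    # fall through with the last draw: still a chain, merely compact
    return SegmentCoordinates(
        source=("coil", "A", 1, n_residues),
        atom_selection=DEFAULT_SELECTION,
        coordinates=coords, residue_sequence=sequence, exceptions=gly)


def make_segment(ss_type: str, n_residues: int, sequence: str,
                 noise_sd: float, rng) -> SegmentCoordinates:
    """One noisy segment of a category (or a coil walk)."""
    if ss_type == RANDOM_COIL:
        seg = _coil_backbone(rng, n_residues, sequence)
    else:
        if ss_type not in DEFAULT_RECIPES:
            raise LibraryError(f"no recipe for category {ss_type!r}")
        seg = build_ideal_backbone(DEFAULT_RECIPES[ss_type], n_residues,
                                   sequence=sequence, name=ss_type)
    coords = seg.coordinates
    if noise_sd > 0:
        coords = coords + rng.normal(0.0, noise_sd, coords.shape)
    return SegmentCoordinates(
        source=seg.source, atom_selection=seg.atom_selection,
        coordinates=coords, residue_sequence=seg.residue_sequence,
        exceptions=seg.exceptions)


def make_instances(ss_type: str, n: int, noise_sd: float, seed: int,
                   n_residues: int = 6, sequence: str | None = None,
                   ) -> tuple[list, pd.DataFrame]:
    """*n* noisy copies of a category's ideal segment plus a manifest.

    Each copy is the recipe backbone plus i.i.d. isotropic Gaussian
    coordinate noise.  The manifest records the true category, window and
    seed; repeated calls with the same arguments are identical.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    if sequence is None:
        sequence = "A" * n_residues
    segs, rows = [], []
    for i in range(n):
        seg = make_segment(ss_type, n_residues, sequence, noise_sd, rng)
        seg = SegmentCoordinates(
            source=(f"{ss_type.replace(' ', '_')}_{i:04d}", "A", 1,
                    n_residues),
            atom_selection=seg.atom_selection,
            coordinates=seg.coordinates,
            residue_sequence=seg.residue_sequence,
            exceptions=seg.exceptions)
        segs.append(seg)
        rows.append({"structure_id": seg.source[0], "true_category": ss_type,
                     "chain": "A", "start": 1, "end": n_residues,
                     "sequence": sequence, "noise_sd": noise_sd,
                     "seed": seed})
    return segs, pd.DataFrame(rows)


@dataclass
class Corpus:
    structures: list              # StructureModel
    manifest: pd.DataFrame
    fasta: str


def make_corpus(spec: CorpusSpec) -> Corpus:
    """A decoy corpus: structures drawn from the category mixture, with
    the motif sequence planted at the recorded window of each planted
    structure.

    Each structure is a single chain whose conformation follows its drawn
    category throughout; the motif window position within the chain is
    randomized and recorded in the manifest.
    """
    rng = np.random.default_rng(spec.seed)
    for name, frac in spec.mixture.items():
        if frac > 0 and name != RANDOM_COIL and name not in DEFAULT_RECIPES:
            raise LibraryError(f"mixture assigns weight to unavailable "
                               f"category {name!r}")
    names = sorted(spec.mixture)
    fracs = np.array([spec.mixture[n] for n in names])
    counts = rng.multinomial(spec.n_structures, fracs)
    m = len(spec.pattern) if spec.pattern else 0

    structures, rows, fasta_parts = [], [], []
    idx = 0
    for name, count in zip(names, counts):
        for _ in range(count):
            length = int(rng.integers(spec.length_range[0],
                                      spec.length_range[1] + 1))
            planted = (spec.pattern is not None
                       and rng.random() < spec.planting_rate)
            if planted:
                start = int(rng.integers(0, length - m + 1))
                lex = _draw_lexicon(rng, spec.pattern)
                flank_l = _random_sequence(rng, start, spec.pattern)
                flank_r = _random_sequence(rng, length - start - m,
                                           spec.pattern)
                seq = flank_l + lex + flank_r
            else:
                start, lex = -1, ""
                seq = _random_sequence(rng, length, spec.pattern)
            seg = make_segment(name, length, seq, spec.noise_sd, rng)
            sid = f"SYN{idx:04d}"
            idx += 1
            seg = SegmentCoordinates(
                source=(sid, "A", 1, length),
                atom_selection=seg.atom_selection,
                coordinates=seg.coordinates,
                residue_sequence=seg.residue_sequence,
                exceptions=seg.exceptions)
            structures.append(segment_to_model(seg, sid))
            fasta_parts.append(f">{sid}\n{seq}")
            rows.append({
                "structure_id": sid, "true_category": name, "chain": "A",
                "length": length, "sequence": seq,
                "motif_start": start + 1 if planted else 0,
                "motif_end": start + m if planted else 0,
                "lexicon": lex,
            })
    manifest = pd.DataFrame(rows, columns=[
        "structure_id", "true_category", "chain", "length", "sequence",
        "motif_start", "motif_end", "lexicon"])
    return Corpus(structures=structures, manifest=manifest,
                  fasta="\n".join(fasta_parts) + ("\n" if fasta_parts else ""))


def write_corpus(corpus: Corpus, directory) -> None:
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    for model in corpus.structures:
        (directory / f"{model.structure_id}.pdb").write_text(
            write_pdb(model))
    (directory / "sequences.fasta").write_text(corpus.fasta)
    corpus.manifest.to_csv(directory / "manifest.tsv", sep="\t", index=False)


def make_disorder_tracks(proportions: tuple, windows, seed: int,
                         ) -> tuple[list, pd.DataFrame]:
    """Binary disorder tracks whose motif-window categories follow the
    target (p_structured, p_unstructured, p_hybrid) proportions.

    *windows* is an iterable of (sequence_id, start, end, length) with
    0-based half-open windows.  Residues outside the window are labelled
    at random.  Returns (tracks, truth manifest).
    """
    from .disorder import DisorderTrack

    p = np.asarray(proportions, dtype=float)
    if abs(p.sum() - 1.0) > 1e-9 or (p < 0).any():
        raise ValueError("proportions must be nonnegative and sum to 1")
    rng = np.random.default_rng(seed)
    tracks, rows = [], []
    cats = np.array(["structured", "unstructured", "hybrid"])
    for seq_id, start, end, length in windows:
        cat = rng.choice(cats, p=p)
        labels = rng.random(length) < 0.5           # True = disordered
        w = end - start
        if cat == "structured":
            labels[start:end] = False
        elif cat == "unstructured":
            labels[start:end] = True
        else:
            if w < 2:
                raise ValueError("hybrid window needs >= 2 residues")
            k = int(rng.integers(1, w))             # 1..w-1 disordered
            picks = rng.permutation(w)[:k]
            labels[start:end] = False
            labels[start + picks] = True
        tracks.append(DisorderTrack(sequence_id=seq_id,
                                    disordered=labels.copy()))
        rows.append({"sequence_id": seq_id, "start": start, "end": end,
                     "true_category": str(cat)})
    return tracks, pd.DataFrame(rows)
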