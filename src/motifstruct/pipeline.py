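"""End-to-end workflow: scan structures for motif sequence matches, keep
the structurally complete ones, score each against the known-positive
template and every canonical secondary-structure category, assign the
lowest-scoring category (random coil when no score is within its
category's variation limit), and tabulate per-motif structure statistics.

Statistics follow the two-denominator convention: the percentage of
*structured lexica* is over lexica observed at least once in the
structure set, and the percentage of *structured instances* is over all
scored instances.  Instances that served as the known-positive query are
excluded from every tabulated count.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .centroid import (
    DEFAULT_WEIGHTS,
    MatchThreshold,
    WeightScheme,
    centroid_score,
    inflate_threshold,
)
from .errors import LibraryError, SizeMismatchError
from .lexicon import MotifPattern, lexicon_size, scan_sequence
from .sslib import RANDOM_COIL, SSLibrary
from .structure_io import (
    DEFAULT_POLICY,
    DEFAULT_SELECTION,
    CompletenessPolicy,
    SegmentCoordinates,
    StructureModel,
    check_completeness,
    extract_segment,
    read_pdb,
)

logger = logging.getLogger(__name__)

POSITIVE_TEMPLATE = "positive template"


@dataclass
class MotifInstance:
    """One motif sequence match in one structure."""

    structure_id: str
    chain: str
    start: int                     # first residue number (structure numbering)
    end: int                       # last residue number, inclusive
    lexicon: str
    segment: SegmentCoordinates | None = None
    complete: bool = False
    is_known_positive_query: bool = False


@dataclass
class ScanSummary:
    n_structures: int
    n_matches: int
    n_complete: int
    skipped: list = field(default_factory=list)


def scan_structures(structures, pattern: MotifPattern,
                    policy: CompletenessPolicy = DEFAULT_POLICY,
                    selection: tuple = DEFAULT_SELECTION,
                    ) -> tuple[list, ScanSummary]:
    """Find every motif instance in a set of structures.

    *structures* is an iterable of :class:`StructureModel` or of paths to
    PDB files; unreadable files are logged, skipped and listed in the run
    summary.  Every (structure, chain, offset) sequence match yields one
    instance; an instance is *complete* — and carries coordinates — only
    when every selected atom is present over its window (glycine CB
    excused).  Incomplete instances are retained but never scored.
    Deterministic order: input order, then chain, then offset.
    """
    models, skipped = [], []
    for item in structures:
        if isinstance(item, StructureModel):
            models.append(item)
            continue
        try:
            from pathlib import Path
            text = Path(item).read_text()
            models.append(read_pdb(text, structure_id=Path(item).stem))
        except Exception as exc:  # noqa: BLE001 - report and continue
            logger.warning("skipping unreadable structure %s: %s", item, exc)
            skipped.append((str(item), str(exc)))
    instances = []
    for model in models:
        for chain in model.chains:
            residues = model.residues(chain)
            seq = model.sequence(chain)
            for match in scan_sequence(seq, pattern, model.structure_id):
                window = residues[match.start : match.end]
                start_num = window[0].number
                end_num = window[-1].number
                required = set(selection)
                ok = True
                for res in window:
                    missing = required - set(res.atoms)
                    if missing == {"CB"} and res.is_glycine:
                        missing = set()
                    if missing:
                        ok = False
                        break
                # the minimal CA rule must hold too
                report = check_completeness(model, chain, start_num, end_num,
                                            policy)
                complete = ok and report.complete
                segment = None
                if complete:
                    segment = extract_segment(model, chain, start_num,
                                              end_num, selection)
                instances.append(MotifInstance(
                    structure_id=model.structure_id, chain=chain,
                    start=start_num, end=end_num,
                    lexicon=match.matched_text, segment=segment,
                    complete=complete))
    summary = ScanSummary(
        n_structures=len(models), n_matches=len(instances),
        n_complete=sum(i.complete for i in instances), skipped=skipped)
    return instances, summary


@dataclass
class PositiveThreshold:
    """Motif-specific acceptance region derived from known positives."""

    template: SegmentCoordinates
    threshold: MatchThreshold
    score_range: tuple           # (min, max) over known positives
    scores: list


def derive_positive_threshold(known_instances,
                              weights: WeightScheme = DEFAULT_WEIGHTS,
                              normalize: bool = True,
                              inflation: float = 0.10,
                              template_index: int = 0) -> PositiveThreshold:
    """Score every known positive against the designated reference
    structure and inflate the maximum by the stated margin.

    The reference (``template_index``, default the first registered) plays
    the role of the solved complex the search is anchored on.  Requires at
    least two known positives with coordinates.
    """
    segments = [
        i.segment if isinstance(i, MotifInstance) else i
        for i in known_instances
    ]
    if any(s is None for s in segments) or len(segments) < 2:
        raise ValueError("need >= 2 known-positive instances with "
                         "coordinates")
    template = segments[template_index]
    scores = [
        centroid_score(template, seg, weights, normalize).value
        for k, seg in enumerate(segments) if k != template_index
    ]
    threshold = inflate_threshold(max(scores), inflation,
                                  weight_scheme=weights.kind,
                                  normalized=normalize)
    return PositiveThreshold(template=template, threshold=threshold,
                             score_range=(min(scores), max(scores)),
                             scores=scores)


@dataclass
class SSAssignment:
    instance: MotifInstance
    best_type: str
    best_score: float
    within_limits: bool

    def __post_init__(self):
        # random coil is exactly the "nothing within limits" outcome
        assert (self.best_type == RANDOM_COIL) == (not self.within_limits)


def assign_structure(instance: MotifInstance, library: SSLibrary,
                     positive: PositiveThreshold | None = None,
                     weights: WeightScheme | None = None,
                     normalize: bool | None = None) -> SSAssignment:
    """Assign one complete instance to its best-scoring category.

    The instance is scored against the canonical template of every
    available category (realised at the instance's window length and
    glycine layout) and, when supplied, against the motif's positive
    template under its own threshold.  The lowest score wins if it is
    within that candidate's limit; otherwise the instance is random coil.
    Ties break by registry order (positive template first) and are logged.
    """
    if instance.segment is None:
        raise ValueError("cannot assign an instance without coordinates")
    weights = weights if weights is not None else library.weights
    normalize = normalize if normalize is not None else library.normalize
    seg = instance.segment
    candidates = []   # (name, score, limit)
    if positive is not None:
        try:
            template = positive.template
            if (template.n_residues == seg.n_residues
                    and seg.gly_positions
                    and not template.gly_positions):
                # drop the template's CB at the instance's glycines so the
                # atom layouts agree
                from .sslib import _trim_segment
                template = _trim_segment(template, seg.n_residues,
                                         seg.gly_positions)
            s = centroid_score(seg, template, weights, normalize).value
            candidates.append((POSITIVE_TEMPLATE, s,
                               positive.threshold.epsilon))
        except SizeMismatchError:
            logger.warning("positive template atom count mismatch for %s; "
                           "skipped", instance.structure_id)
    for name in library.available_types:
        try:
            template = library.canonical_of(name, seg.n_residues,
                                            seg.gly_positions)
            s = centroid_score(seg, template, weights, normalize).value
        except (SizeMismatchError, LibraryError) as exc:
            logger.warning("template %s skipped for %s: %s", name,
                           instance.structure_id, exc)
            continue
        candidates.append((name, s, library.variation_limit(name)))
    if not candidates:
        raise ValueError("every template was skipped; nothing to assign")
    best_score = min(s for _, s, _ in candidates)
    ties = [c for c in candidates if c[1] == best_score]
    if len(ties) > 1:
        logger.info("score tie for %s between %s; registry order breaks it",
                    instance.structure_id, [t[0] for t in ties])
    name, score, limit = ties[0]
    if score <= limit:
        return SSAssignment(instance=instance, best_type=name,
                            best_score=score, within_limits=True)
    return SSAssignment(instance=instance, best_type=RANDOM_COIL,
                        best_score=score, within_limits=False)


@dataclass
class LexiconStatistics:
    """Per-motif lexical-set structure statistics.

    ``n_lexica`` is pattern-theoretic (the size of the lexical set);
    ``n_lexica_observed`` counts lexica with at least one instance in the
    structure set; ``n_structured_lexica`` counts lexica with at least one
    instance in the correct category.  Percentages use the observed-lexica
    and all-instances denominators respectively; both denominators are
    carried so either convention can be reported.
    """

    n_lexica: int
    n_lexica_observed: int
    n_structured_lexica: int
    n_instances: int
    n_structured_instances: int

    def __post_init__(self):
        if not (self.n_structured_lexica <= self.n_lexica_observed
                <= self.n_lexica):
            raise ValueError("lexicon counts violate "
                             "structured <= observed <= total")

    @property
    def pct_structured_lexica(self) -> float:
        if self.n_lexica_observed == 0:
            return 0.0
        return 100.0 * self.n_structured_lexica / self.n_lexica_observed

    @property
    def pct_structured_instances(self) -> float:
        if self.n_instances == 0:
            return 0.0
        return 100.0 * self.n_structured_instances / self.n_instances

    def printed(self, decimals_lexica: int = 0,
                decimals_instances: int = 2) -> tuple:
        """The two percentages at a chosen printed precision."""
        return (round(self.pct_structured_lexica, decimals_lexica),
                round(self.pct_structured_instances, decimals_instances))


def tabulate(assignments, pattern: MotifPattern, correct_type: str,
             ) -> tuple[pd.DataFrame, LexiconStatistics]:
    """Per-category instance counts and lexicon statistics for one motif.

    *correct_type* names the category counted as "correct structure" —
    the positive-template match when a solved positive exists, otherwise
    the motif's declared canonical category.  Known-positive query
    instances are excluded from every count.  The per-category counts
    always sum to the total scored instances.
    """
    kept = [a for a in assignments
            if not a.instance.is_known_positive_query]
    counts: dict = {}
    for a in kept:
        counts[a.best_type] = counts.get(a.best_type, 0) + 1
    table = pd.DataFrame(
        [{"category": k, "count": v} for k, v in sorted(counts.items())])
    total = sum(counts.values())
    table = pd.concat(
        [table, pd.DataFrame([{"category": "Total", "count": total}])],
        ignore_index=True)

    observed = {a.instance.lexicon for a in kept}
    structured = {a.instance.lexicon for a in kept
                  if a.best_type == correct_type}
    stats = LexiconStatistics(
        n_lexica=lexicon_size(pattern),
        n_lexica_observed=len(observed),
        n_structured_lexica=len(structured),
        n_instances=total,
        n_structured_instances=sum(
            a.best_type == correct_type for a in kept),
    )
    return table, stats


@dataclass
class KnownPositive:
    protein: str
    site: str
    lexicon: str
    structure_ref: str | None = None


@dataclass
class KnownPositiveSet:
    """Experimentally validated motif instances and their correct category."""

    entries: list
    correct_ss_type: str

    def __post_init__(self):
        if not self.entries:
            raise ValueError("known-positive set must be nonempty")

    def check_pattern(self, pattern: MotifPattern) -> None:
        bad = [e.lexicon for e in self.entries
               if not pattern.matches_window(e.lexicon)]
        if bad:
            raise ValueError(f"known positives {bad} do not match the "
                             f"pattern {pattern.raw_text}")


@dataclass
class RecallResult:
    n_instances: int
    n_instances_recovered: int
    n_lexica: int
    n_lexica_recovered: int

    @property
    def instance_recall_pct(self) -> float:
        return 100.0 * self.n_instances_recovered / self.n_instances

    @property
    def lexicon_recall_pct(self) -> float:
        return 100.0 * self.n_lexica_recovered / self.n_lexica


def validate_known_positives(known: KnownPositiveSet,
                             structured_lexica) -> RecallResult:
    """Recall of the structure-refined definition on the known positives.

    Instance recall: fraction of known-positive instances whose lexicon
    is among the structurally confirmed lexica.  Lexicon recall: same at
    the level of distinct lexica.
    """
    structured = set(structured_lexica)
    n_inst = len(known.entries)
    n_rec = sum(e.lexicon in structured for e in known.entries)
    distinct = {e.lexicon for e in known.entries}
    return RecallResult(
        n_instances=n_inst, n_instances_recovered=n_rec,
        n_lexica=len(distinct),
        n_lexica_recovered=len(distinct & structured))


@dataclass
class CrossMotifSummary:
    mean_pct_structured_lexica: float
    range_pct_structured_lexica: tuple
    mean_pct_structured_instances: float
    range_pct_structured_instances: tuple


def summarize_across_motifs(per_motif) -> CrossMotifSummary:
    """Unweighted mean and min-max of the two percentages across motifs.

    Accepts :class:`LexiconStatistics` objects or bare
    (pct_structured_lexica, pct_structured_instances) pairs.
    """
    lex, inst = [], []
    for item in per_motif:
        if isinstance(item, LexiconStatistics):
            lex.append(item.pct_structured_lexica)
            inst.append(item.pct_structured_instances)
        else:
            a, b = item
            lex.append(float(a))
            inst.append(float(b))
    if not lex:
        raise ValueError("need at least one motif")
    return CrossMotifSummary(
        mean_pct_structured_lexica=float(np.mean(lex)),
        range_pct_structured_lexica=(min(lex), max(lex)),
        mean_pct_structured_instances=float(np.mean(inst)),
        range_pct_structured_instances=(min(inst), max(inst)),
    )


def assignments_frame(assignments) -> pd.DataFrame:
    """Flat TSV-ready view of a list of assignments."""
    return pd.DataFrame([
        {"structure_id": a.instance.structure_id,
         "chain": a.instance.chain,
         "start": a.instance.start, "end": a.instance.end,
         "lexicon": a.instance.lexicon,
         "best_type": a.best_type,
         "best_score": a.best_score,
         "within_limits": a.within_limits,
         "known_positive_query": a.instance.is_known_positive_query}
        for a in assignments
    ])
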