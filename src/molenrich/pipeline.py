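"""End-to-end orchestration of the three analysis modes.

parse -> branch/relation restriction -> annotate -> test -> BH-correct ->
prune -> package.  The background population is always the full set of
molecules of the ontology actually analysed (i.e. after branch restriction).
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, field
from typing import Iterable, NamedTuple

from .ontology import (
    DISPLAY_RELATIONS,
    HAS_PART,
    HAS_ROLE,
    IS_A,
    AnnotationIndex,
    OntologyGraph,
    build_annotation_index,
    restrict_branch,
)
from .pruning import (
    STRATEGY_PRESETS,
    PruningStrategy,
    ResultGraph,
    apply_strategy,
)
from .saddlesum import DegenerateWeightsWarning, WeightedSample, weighted_enrichment
from .stats import MODE_ENTITIES, EnrichmentRow, InputError, plain_enrichment

MODES = ("plain", "weighted", "fragment")
BRANCHES = ("structural", "role", "all")

#: CURIE prefix applied to bare numeric ids in input files.
DEFAULT_ID_PREFIX = "CHEBI"


@dataclass
class AnalysisConfig:
    """Knobs for one analysis run.

    ``fragment`` mode forces the structural branch.  ``strategy`` may be a
    :class:`PruningStrategy` or a preset name; ``None`` selects the default
    preset for the mode.
    """

    mode: str = "plain"
    branch: str = "all"
    alpha: float = 0.05
    population_mode: str = MODE_ENTITIES
    strategy: PruningStrategy | str | None = None
    propagate_has_part: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if self.mode not in MODES:
            raise InputError(f"unknown mode {self.mode!r}")
        if self.branch not in BRANCHES:
            raise InputError(f"unknown branch {self.branch!r}")
        if self.mode == "fragment":
            self.branch = "structural"
        if not 0.0 < self.alpha < 1.0:
            raise InputError("alpha must be in (0, 1)")

    def annotation_relations(self) -> frozenset[str]:
        rels = {IS_A, HAS_ROLE}
        if self.propagate_has_part:
            rels.add(HAS_PART)
        return frozenset(rels)

    def resolve_strategy(self) -> PruningStrategy:
        if isinstance(self.strategy, PruningStrategy):
            return self.strategy
        name = self.strategy or f"{self.mode}_default"
        if name not in STRATEGY_PRESETS:
            raise InputError(f"unknown strategy preset {name!r}")
        return STRATEGY_PRESETS[name](self.alpha)


@dataclass
class RunReport:
    """Counts, warnings and the pruner log for one run."""

    n_submitted: int = 0
    n_recognised: int = 0
    unrecognised_ids: list[str] = field(default_factory=list)
    n_duplicates: int = 0
    population_entities: int = 0
    population_classes: int = 0
    n_tested_classes: int = 0
    pruner_log: list[tuple[str, str, int]] = field(default_factory=list)
    warnings: list[str] = field(default_factory=list)


class AnalysisResult(NamedTuple):
    rows: list[EnrichmentRow]
    graph: ResultGraph
    report: RunReport


_BARE_ID_RE = re.compile(r"^\d+$")


def _normalise_id(token: str, lineno: int, prefix: str) -> str:
    token = token.strip()
    if _BARE_ID_RE.match(token):
        return f"{prefix}:{token}"
    if ":" in token:
        return token
    raise InputError(f"line {lineno}: unrecognised identifier {token!r}")


def validate_input(
    lines: Iterable[str], id_prefix: str = DEFAULT_ID_PREFIX
) -> WeightedSample:
    """Parse an id / id<TAB>weight sample file into a :class:`WeightedSample`.

    Bare numeric ids are normalised to CURIEs; blank lines and ``#``
    comments are skipped; duplicates are merged keeping the maximum weight.
    Mixing weighted and unweighted rows is an error.
    """
    entries: dict[str, float | None] = {}
    weighted: bool | None = None
    n_dup = 0
    for lineno, raw in enumerate(lines, start=1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split("\t")
        mol_id = _normalise_id(parts[0], lineno, id_prefix)
        weight: float | None = None
        if len(parts) > 1 and parts[1].strip():
            try:
                weight = float(parts[1])
            except ValueError as exc:
                raise InputError(
                    f"line {lineno}: weight not parseable: {parts[1]!r}"
                ) from exc
            if not 0.0 <= weight <= 1.0:
                raise InputError(f"line {lineno}: weight outside [0, 1]: {weight}")
        row_weighted = weight is not None
        if weighted is None:
            weighted = row_weighted
        elif weighted != row_weighted:
            raise InputError(
                f"line {lineno}: mixed weighted and unweighted rows in input"
            )
        if mol_id in entries:
            n_dup += 1
            if weight is not None:
                prev = entries[mol_id]
                entries[mol_id] = weight if prev is None else max(prev, weight)
        else:
            entries[mol_id] = weight
    if not entries:
        raise InputError("input contains no identifiers")
    return WeightedSample(entries=list(entries.items()), n_duplicates=n_dup)


def run_analysis(
    ontology: OntologyGraph,
    sample: WeightedSample,
    config: AnalysisConfig,
) -> AnalysisResult:
    """Run one full enrichment analysis.

    Returns rows sorted by (p_adj, p_raw, class_id), the pruned result
    graph whose retained tested nodes carry their rows, and a run report.
    """
    if not ontology.terms:
        raise InputError("ontology is empty")
    if config.mode == "plain" and sample.is_weighted:
        raise InputError("plain mode cannot use weighted input rows")
    if config.mode in ("weighted", "fragment") and not sample.is_weighted:
        raise InputError(f"{config.mode} mode requires weights on every input row")

    analysed = restrict_branch(ontology, config.branch)
    index = build_annotation_index(analysed, config.annotation_relations())

    submitted = sample.ids()
    recognised = [m for m in submitted if m in index.molecule_ids]
    unrecognised = sorted(set(submitted) - set(recognised))
    if not recognised:
        raise InputError(
            "no submitted identifier matches a molecule in the analysed "
            "ontology; unrecognised: " + ", ".join(unrecognised)
        )

    report = RunReport(
        n_submitted=len(submitted),
        n_recognised=len(recognised),
        unrecognised_ids=unrecognised,
        n_duplicates=sample.n_duplicates,
        population_entities=index.population_size_entities,
        population_classes=index.population_size_classes,
    )
    if unrecognised:
        report.warnings.append(
            f"{len(unrecognised)} identifier(s) not found in the analysed "
            "ontology; the recognised molecules act as a sample of the "
            "complete submitted set"
        )

    if config.mode == "plain":
        rows = plain_enrichment(index, recognised, config.population_mode)
    else:
        reduced = WeightedSample(
            entries=[(m, w) for m, w in sample.entries if m in index.molecule_ids]
        )
        with warnings.catch_warnings(record=True) as caught:
            warnings.simplefilter("always", DegenerateWeightsWarning)
            rows = weighted_enrichment(index, reduced, config.population_mode)
        for w in caught:
            report.warnings.append(str(w.message))
    report.n_tested_classes = len(rows)

    result_graph = ResultGraph.from_ontology(analysed, rows, DISPLAY_RELATIONS)
    pruned, log = apply_strategy(result_graph, config.resolve_strategy())
    report.pruner_log = log
    return AnalysisResult(rows=rows, graph=pruned, report=report)
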