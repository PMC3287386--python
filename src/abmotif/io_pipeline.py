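"""File formats, configuration and pipeline orchestration.

The pipeline mirrors how the method is run in practice:

1. read per-organism association networks (STRING-dialect links files,
   optionally projected from protein to COG level through a mapping table)
   and the organism phenotype table;
2. build the two-typed, divided network at a combined-score edge threshold;
3. pick the statistically significant non-redundant (alpha, beta) pairs, or
   accept an explicit list;
4. enumerate (alpha, beta)-cliques, deduplicate across pairs, attach the
   hypergeometric bias p-value and (when a distance matrix is supplied) the
   phylogenetic diversity score, and write a canonical sorted module table.

Two study-design helpers sit on top: an edge-threshold scan that walks a
descending score ladder until a validation COG set is recovered with the
requested accuracy, and a genus-grouped subsampling check that measures how
stable the top-ranked modules are under cohort perturbation.

All outputs are byte-deterministic for a fixed config and seed.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import yaml

from . import __version__
from .errors import (
    AbmotifError,
    ConfigurationError,
    InputError,
    ParameterError,
    ParseError,
)
from .motif_finder import (
    BoundMode,
    ModuleClique,
    enumerate_ab_cliques,
    sort_modules,
)
from .network_model import (
    DividedNetwork,
    FunctionalAssociationNetwork,
    OrganismAnnotation,
    Phenotype,
    Vertex,
    build_divided_network,
    project_proteins_to_cogs,
)
from .phylo import PhyloDistanceMatrix, phylo_score
from .significance import (
    AlphaBetaPair,
    clique_significance,
    hypergeometric_upper_tail,
    select_ab_pairs,
)

logger = logging.getLogger(__name__)


def default_threshold_ladder() -> tuple[int, ...]:
    """Descending combined-score ladder 999, 950, 900, ..., 500."""
    return (999,) + tuple(range(950, 499, -50))


# ---------------------------------------------------------------------------
# readers
# ---------------------------------------------------------------------------


def _is_int(text: str) -> bool:
    try:
        int(text)
        return True
    except ValueError:
        return False


def read_links(
    path, organism_id: str | None = None
) -> dict[str, list[tuple[str, str, int]]]:
    """Read a STRING-dialect links file into per-organism edge triples.

    Whitespace- or tab-separated. Three columns (node1, node2,
    combined_score) describe a single organism's network — ``organism_id``
    then names it (defaulting to the file stem). Four columns prepend an
    organism column, allowing one file per cohort. An optional header line is
    recognised by a non-numeric score field.
    """
    path = Path(path)
    stem = path.stem
    if stem.endswith(".links"):
        stem = stem[: -len(".links")]
    per_org: dict[str, list[tuple[str, str, int]]] = {}
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            parts = raw.split()
            if not parts or raw.lstrip().startswith("#"):
                continue
            if len(parts) == 3:
                org = organism_id if organism_id is not None else stem
                a, b, score = parts
            elif len(parts) == 4:
                org, a, b, score = parts
            else:
                raise ParseError(
                    f"expected 3 or 4 columns, got {len(parts)}", line=lineno
                )
            if not _is_int(score):
                if lineno == 1:
                    continue  # header
                raise ParseError(f"malformed score {score!r}", line=lineno)
            score_i = int(score)
            if not 0 <= score_i <= 999:
                raise ParseError(
                    f"score {score_i} outside [0, 999]", line=lineno
                )
            per_org.setdefault(org, []).append((a, b, score_i))
    if not per_org:
        # an edge-less per-organism file still declares its organism
        per_org[organism_id if organism_id is not None else stem] = []
    return per_org


def read_phenotype_table(path) -> list[OrganismAnnotation]:
    """TSV of (organism_id, positive|negative), optional header."""
    annotations: list[OrganismAnnotation] = []
    seen: set[str] = set()
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            parts = raw.split()
            if not parts or raw.lstrip().startswith("#"):
                continue
            if len(parts) != 2:
                raise ParseError(
                    f"expected 2 columns, got {len(parts)}", line=lineno
                )
            org, value = parts
            if lineno == 1 and value.lower() in ("phenotype", "type"):
                continue
            try:
                phenotype = Phenotype.parse(value)
            except ParseError:
                raise ParseError(
                    f"unrecognised phenotype {value!r}", line=lineno
                ) from None
            if org in seen:
                raise ConfigurationError(f"duplicate organism {org!r} in phenotype table")
            seen.add(org)
            annotations.append(OrganismAnnotation(org, phenotype))
    return annotations


def read_cog_mapping(path) -> dict[str, dict[str, str]]:
    """TSV of (organism_id, protein_id, cog_id) -> per-organism mapping."""
    mapping: dict[str, dict[str, str]] = {}
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            parts = raw.split()
            if not parts or raw.lstrip().startswith("#"):
                continue
            if len(parts) != 3:
                raise ParseError(
                    f"expected 3 columns, got {len(parts)}", line=lineno
                )
            org, protein, cog = parts
            if lineno == 1 and cog.lower() in ("cog", "cog_id"):
                continue
            mapping.setdefault(org, {})[protein] = cog
    return mapping


def read_distance_matrix(path) -> PhyloDistanceMatrix:
    """Labelled square TSV or PHYLIP-style square distance matrix."""
    with open(path) as fh:
        lines = [ln for ln in (l.rstrip("\n") for l in fh) if ln.strip()]
    if not lines:
        raise ParseError("empty distance matrix file", line=1)
    first = lines[0].split()
    if len(first) == 1 and _is_int(first[0]):  # PHYLIP square
        n = int(first[0])
        ids, rows = [], []
        for lineno, ln in enumerate(lines[1:], start=2):
            parts = ln.split()
            if len(parts) != n + 1:
                raise ParseError(
                    f"expected name + {n} distances", line=lineno
                )
            ids.append(parts[0])
            rows.append([float(x) for x in parts[1:]])
        if len(ids) != n:
            raise ParseError(f"expected {n} rows, got {len(ids)}")
        return PhyloDistanceMatrix.from_array(ids, np.array(rows))
    # labelled TSV: header row of ids (first cell empty or a label)
    header = first
    col_ids = header[1:] if not _is_float(header[0]) else header
    ids, rows = [], []
    for lineno, ln in enumerate(lines[1:], start=2):
        parts = ln.split()
        if len(parts) != len(col_ids) + 1:
            raise ParseError(
                f"expected name + {len(col_ids)} distances", line=lineno
            )
        ids.append(parts[0])
        try:
            rows.append([float(x) for x in parts[1:]])
        except ValueError as exc:
            raise ParseError(str(exc), line=lineno) from None
    if ids != list(col_ids):
        raise ParseError("row ids do not match column ids")
    return PhyloDistanceMatrix.from_array(ids, np.array(rows))


def _is_float(text: str) -> bool:
    try:
        float(text)
        return True
    except ValueError:
        return False


def load_networks(
    links_paths: Sequence, mapping_path=None
) -> list[FunctionalAssociationNetwork]:
    """Read one or more links files; project proteins to COGs if mapped.

    A sidecar ``<organism>.cogs.txt`` next to a links file lists COGs present
    in the organism without any scored association (isolated vertices); they
    still participate in orthology edges, so presence must survive I/O.
    """
    edges_by_org: dict[str, list[tuple[str, str, int]]] = {}
    extra_cogs: dict[str, set[str]] = {}
    for p in links_paths:
        p = Path(p)
        for org, triples in read_links(p).items():
            edges_by_org.setdefault(org, []).extend(triples)
            sidecar = p.parent / f"{org}.cogs.txt"
            if sidecar.exists():
                extra_cogs.setdefault(org, set()).update(
                    sidecar.read_text().split()
                )
    mapping = read_cog_mapping(mapping_path) if mapping_path else None
    networks = []
    for org in sorted(edges_by_org):
        triples = edges_by_org[org]
        if mapping is not None:
            net, report = project_proteins_to_cogs(
                triples, mapping.get(org, {}), organism_id=org
            )
            if report.unmapped_proteins:
                logger.info(
                    "%s: dropped %d unmapped proteins",
                    org,
                    len(report.unmapped_proteins),
                )
            networks.append(net)
        else:
            networks.append(
                FunctionalAssociationNetwork.from_edge_list(
                    org, triples, extra_cogs=extra_cogs.get(org, ())
                )
            )
    return networks


# ---------------------------------------------------------------------------
# module table I/O
# ---------------------------------------------------------------------------

MODULE_COLUMNS = (
    "cog_set",
    "positive_orgs",
    "negative_orgs",
    "alpha_count",
    "beta_count",
    "p_value",
    "phylo_score",
)

_NA = "NA"


def _fmt_float(value: float | None) -> str:
    return _NA if value is None else repr(float(value))


def _join(items: Iterable[str]) -> str:
    return ";".join(sorted(items))


def write_modules(modules: Sequence[ModuleClique], path) -> None:
    """Write the module table: TSV plus an exact JSON mirror.

    The TSV flattens each module to its COG and organism sets (semicolon
    joined, sorted); the JSON sidecar (same stem, ``.json``) additionally
    stores the exact vertex list, which the TSV cannot represent for the
    rare non-product cliques.
    """
    path = Path(path)
    modules = sort_modules(modules)
    lines = ["\t".join(MODULE_COLUMNS)]
    for m in modules:
        lines.append(
            "\t".join(
                (
                    _join(m.cog_set),
                    _join(m.positive_orgs),
                    _join(m.negative_orgs),
                    str(m.alpha_count),
                    str(m.beta_count),
                    _fmt_float(m.p_value),
                    _fmt_float(m.phylo_score),
                )
            )
        )
    path.write_text("\n".join(lines) + "\n")
    payload = [
        {
            "cog_set": sorted(m.cog_set),
            "positive_orgs": sorted(m.positive_orgs),
            "negative_orgs": sorted(m.negative_orgs),
            "alpha_count": m.alpha_count,
            "beta_count": m.beta_count,
            "p_value": m.p_value,
            "phylo_score": m.phylo_score,
            "is_product": m.is_product,
            "vertices": [list(v) for v in sorted(m.vertices)],
        }
        for m in modules
    ]
    path.with_suffix(".json").write_text(
        json.dumps(payload, indent=1, sort_keys=True) + "\n"
    )


def read_modules(path) -> list[ModuleClique]:
    """Read a module table written by :func:`write_modules`.

    ``.json`` inputs restore the exact vertex sets; ``.tsv`` inputs
    reconstruct vertices as the organism x COG product (exact for product
    modules, which is everything the TSV can encode).
    """
    path = Path(path)
    if path.suffix == ".json":
        records = json.loads(path.read_text())
        out = []
        for rec in records:
            vertices = frozenset(Vertex(o, c) for o, c in rec["vertices"])
            out.append(
                ModuleClique(
                    vertices=vertices,
                    cog_set=frozenset(rec["cog_set"]),
                    positive_orgs=frozenset(rec["positive_orgs"]),
                    negative_orgs=frozenset(rec["negative_orgs"]),
                    is_product=rec["is_product"],
                    p_value=rec["p_value"],
                    phylo_score=rec["phylo_score"],
                )
            )
        return out
    out = []
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if tuple(header) != MODULE_COLUMNS:
            raise ParseError(f"unexpected header {header!r}", line=1)
        for lineno, raw in enumerate(fh, start=2):
            if not raw.strip():
                continue
            parts = raw.rstrip("\n").split("\t")
            if len(parts) != len(MODULE_COLUMNS):
                raise ParseError(
                    f"expected {len(MODULE_COLUMNS)} columns, got {len(parts)}",
                    line=lineno,
                )
            cogs, pos, neg, a_count, b_count, p_val, s_p = parts
            cog_set = frozenset(c for c in cogs.split(";") if c)
            pos_set = frozenset(o for o in pos.split(";") if o)
            neg_set = frozenset(o for o in neg.split(";") if o)
            try:
                if int(a_count) != len(pos_set) or int(b_count) != len(neg_set):
                    raise ParseError("type counts disagree with sets", line=lineno)
            except ValueError:
                raise ParseError("malformed type count", line=lineno) from None
            try:
                p_value = None if p_val == _NA else float(p_val)
                s_value = None if s_p == _NA else float(s_p)
            except ValueError:
                raise ParseError("malformed score field", line=lineno) from None
            orgs = pos_set | neg_set
            vertices = frozenset(Vertex(o, c) for o in orgs for c in cog_set)
            out.append(
                ModuleClique(
                    vertices=vertices,
                    cog_set=cog_set,
                    positive_orgs=pos_set,
                    negative_orgs=neg_set,
                    is_product=True,
                    p_value=p_value,
                    phylo_score=s_value,
                )
            )
    return out


def write_cohort(cohort, out_dir, *, distance_seed: int | None = None) -> dict:
    """Write a synthetic cohort in the pipeline's own input dialects.

    Produces one links TSV per organism, a phenotype TSV, a distance-matrix
    TSV (seeded from the cohort seed unless ``distance_seed`` is given) and
    a ground-truth JSON. Returns the path map.
    """
    from .synthetic_data import generate_distance_matrix

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    links_paths = []
    for net in cohort.networks:
        p = out_dir / f"{net.organism_id}.links.tsv"
        lines = ["node1\tnode2\tcombined_score"]
        for (a, b), score in sorted(net.edges.items()):
            lines.append(f"{a}\t{b}\t{score}")
        # isolated COGs have no edge rows; record them so presence survives
        isolated = sorted(
            net.cogs - {c for pair in net.edges for c in pair}
        )
        p.write_text("\n".join(lines) + "\n")
        if isolated:
            (out_dir / f"{net.organism_id}.cogs.txt").write_text(
                "\n".join(isolated) + "\n"
            )
        links_paths.append(str(p))
    pheno = out_dir / "phenotypes.tsv"
    pheno.write_text(
        "\n".join(
            f"{a.organism_id}\t{a.phenotype.value}" for a in cohort.annotations
        )
        + "\n"
    )
    ids = [a.organism_id for a in cohort.annotations]
    dm = generate_distance_matrix(
        ids, cohort.params.seed if distance_seed is None else distance_seed
    )
    dm_path = out_dir / "distances.tsv"
    header = "organism\t" + "\t".join(ids)
    rows = [header]
    for i, org in enumerate(ids):
        rows.append(
            org + "\t" + "\t".join(repr(x) for x in dm.distances[i].tolist())
        )
    dm_path.write_text("\n".join(rows) + "\n")
    gt_path = out_dir / "ground_truth.json"
    gt_path.write_text(
        json.dumps(cohort.ground_truth, indent=1, sort_keys=True) + "\n"
    )
    return {
        "links": links_paths,
        "phenotypes": str(pheno),
        "distances": str(dm_path),
        "ground_truth": str(gt_path),
    }


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------


@dataclass
class PipelineConfig:
    """Everything one pipeline run depends on.

    Exactly one of ``pairs`` (explicit (alpha, beta) list) or
    ``auto_select`` must be active.
    """

    links: tuple[str, ...] = ()
    mapping: str | None = None
    phenotypes: str | None = None
    distances: str | None = None
    validation_cogs: str | None = None
    edge_threshold: int = 700
    p_threshold: float = 0.005
    pairs: tuple[tuple[int, int], ...] | None = None
    auto_select: bool = True
    bound_mode: str = "alpha_beta"
    min_cogs: int = 1
    out_dir: str | None = None
    seed: int = 0
    log_level: str = "INFO"

    def __post_init__(self):
        if (self.pairs is not None) == bool(self.auto_select):
            raise ConfigurationError(
                "exactly one of explicit pairs / auto_select must be active"
            )
        if not 0 <= self.edge_threshold <= 999:
            raise ParameterError("edge_threshold outside [0, 999]")
        if not 0 < self.p_threshold <= 1:
            raise ParameterError("p_threshold outside (0, 1]")
        if self.min_cogs < 1:
            raise ParameterError("min_cogs must be >= 1")
        BoundMode.parse(self.bound_mode)

    @classmethod
    def from_file(cls, path, **overrides) -> "PipelineConfig":
        try:
            text = Path(path).read_text()
        except OSError as exc:
            raise ConfigurationError(f"cannot read config file: {exc}") from exc
        raw = yaml.safe_load(text) or {}
        if not isinstance(raw, dict):
            raise ConfigurationError("config file must be a mapping")
        raw.update({k: v for k, v in overrides.items() if v is not None})
        if "links" in raw and isinstance(raw["links"], (str, Path)):
            raw["links"] = (str(raw["links"]),)
        if raw.get("pairs") is not None:
            raw["pairs"] = tuple((int(a), int(b)) for a, b in raw["pairs"])
            raw.setdefault("auto_select", False)
        known = {f.name for f in cls.__dataclass_fields__.values()}  # type: ignore[attr-defined]
        unknown = set(raw) - known
        if unknown:
            raise ConfigurationError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)


# ---------------------------------------------------------------------------
# core orchestration
# ---------------------------------------------------------------------------


def enumerate_union(
    network: DividedNetwork,
    pairs: Sequence[AlphaBetaPair | tuple[int, int]],
    bound_mode: "str | BoundMode" = BoundMode.ALPHA_BETA,
) -> list[ModuleClique]:
    """Deduplicated union of (alpha, beta)-cliques over several pairs.

    A maximal clique belongs to a pair's output purely through its type
    counts, so one enumeration at (min alpha, max beta) followed by an
    any-pair filter equals the union of per-pair enumerations.
    """
    norm = [
        (p.alpha, p.beta) if isinstance(p, AlphaBetaPair) else (int(p[0]), int(p[1]))
        for p in pairs
    ]
    if not norm:
        return []
    amin = min(a for a, _ in norm)
    bmax = max(b for _, b in norm)
    modules = enumerate_ab_cliques(network, amin, bmax, bound_mode)
    return [
        m
        for m in modules
        if any(m.alpha_count >= a and m.beta_count <= b for a, b in norm)
    ]


def run_on_cohort(
    networks: Sequence[FunctionalAssociationNetwork],
    annotations: Sequence[OrganismAnnotation],
    dm: PhyloDistanceMatrix | None = None,
    *,
    edge_threshold: int = 700,
    pairs: Sequence[tuple[int, int]] | None = None,
    p_threshold: float = 0.005,
    bound_mode: "str | BoundMode" = BoundMode.ALPHA_BETA,
    min_cogs: int = 1,
) -> tuple[list[ModuleClique], list[AlphaBetaPair], DividedNetwork]:
    """In-memory pipeline core: build, select, enumerate, score, filter."""
    n_pos = sum(1 for a in annotations if a.phenotype is Phenotype.POSITIVE)
    n_neg = len(annotations) - n_pos
    if n_pos == 0:
        raise ConfigurationError(
            "cohort contains no phenotype-positive organism",
            code="E_NO_POSITIVES",
        )
    network = build_divided_network(networks, annotations, edge_threshold)
    if pairs is None:
        selected = select_ab_pairs(n_pos, n_neg, p_threshold)
        if not selected:
            logger.warning(
                "no (alpha, beta) pair reaches p <= %g for %d/%d cohort",
                p_threshold,
                n_pos,
                n_neg,
            )
    else:
        selected = [
            AlphaBetaPair(
                a, b, hypergeometric_upper_tail(n_pos + n_neg, n_pos, a + b, a)
            )
            for a, b in pairs
        ]
    modules = enumerate_union(network, selected, bound_mode)
    scored = []
    for m in modules:
        if len(m.cog_set) < min_cogs:
            continue
        p = clique_significance(m, n_pos, n_neg)
        s_p = None
        if dm is not None:
            s_p = phylo_score(m.positive_orgs, m.negative_orgs, dm)
        scored.append(m.with_scores(p_value=p, phylo_score=s_p))
    return sort_modules(scored), selected, network


@dataclass
class PipelineResult:
    modules: list[ModuleClique]
    pairs: list[AlphaBetaPair]
    network_summary: dict
    paths: dict[str, str] = field(default_factory=dict)


def run_pipeline(config: PipelineConfig) -> PipelineResult:
    """File-level pipeline: read inputs, run, write outputs and a manifest."""
    logging.getLogger("abmotif").setLevel(config.log_level.upper())
    if not config.links:
        raise ConfigurationError("no links files configured")
    if config.phenotypes is None:
        raise ConfigurationError("no phenotype table configured")
    try:
        networks = load_networks(config.links, config.mapping)
        annotations = read_phenotype_table(config.phenotypes)
        dm = (
            read_distance_matrix(config.distances)
            if config.distances
            else None
        )
    except OSError as exc:
        raise InputError(f"unreadable input: {exc}", code="E_UNREADABLE") from exc
    net_orgs = {n.organism_id for n in networks}
    ann_orgs = {a.organism_id for a in annotations}
    if net_orgs - ann_orgs:
        raise ConfigurationError(
            f"networks without phenotype annotation: {sorted(net_orgs - ann_orgs)}",
            code="E_ORG_MISMATCH",
        )
    annotations = [a for a in annotations if a.organism_id in net_orgs]
    modules, pairs, network = run_on_cohort(
        networks,
        annotations,
        dm,
        edge_threshold=config.edge_threshold,
        pairs=config.pairs,
        p_threshold=config.p_threshold,
        bound_mode=config.bound_mode,
        min_cogs=config.min_cogs,
    )
    if not modules:
        logger.warning("no module satisfies any selected (alpha, beta) pair")
    result = PipelineResult(
        modules=modules,
        pairs=pairs,
        network_summary=network.summary(),
    )
    if config.out_dir:
        out_dir = Path(config.out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        table = out_dir / "modules.tsv"
        write_modules(modules, table)
        manifest = {
            "config": {
                k: (list(v) if isinstance(v, tuple) else v)
                for k, v in asdict(config).items()
            },
            "seed": config.seed,
            "selected_pairs": [
                {"alpha": p.alpha, "beta": p.beta, "p_value": p.p_value}
                for p in pairs
            ],
            "network": result.network_summary,
            "n_modules": len(modules),
            "abmotif_version": __version__,
        }
        (out_dir / "manifest.json").write_text(
            json.dumps(manifest, indent=1, sort_keys=True) + "\n"
        )
        result.paths = {
            "modules_tsv": str(table),
            "modules_json": str(table.with_suffix(".json")),
            "manifest": str(out_dir / "manifest.json"),
        }
    return result


# ---------------------------------------------------------------------------
# edge-threshold selection
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ThresholdRow:
    threshold: int
    accuracy: float
    n_modules: int
    unique_cogs: int
    delta_cogs: int  # change vs the previous (higher) ladder step


@dataclass
class ThresholdReport:
    selected: int
    target_reached: bool
    rows: list[ThresholdRow]


def select_edge_threshold(
    networks: Sequence[FunctionalAssociationNetwork],
    annotations: Sequence[OrganismAnnotation],
    validation_cogs: Iterable[str],
    *,
    accuracy_target: float = 0.75,
    ladder: Sequence[int] | None = None,
    pairs: Sequence[tuple[int, int]] | None = None,
    p_threshold: float = 0.005,
    bound_mode: "str | BoundMode" = BoundMode.ALPHA_BETA,
    min_cogs: int = 1,
) -> ThresholdReport:
    """Walk a descending score ladder until validation accuracy is reached.

    For each ladder value the full pipeline is run and *accuracy* is the
    recall of the validation set: the fraction of validation COGs appearing
    in at least one output module. The first ladder value (descending order)
    reaching ``accuracy_target`` is selected; if none does, the
    best-accuracy value is returned with ``target_reached=False`` and a
    warning. The unique-COG count per threshold and its successive
    differences are reported as a secondary diagnostic, never auto-applied.
    """
    validation = set(validation_cogs)
    if not validation:
        raise ParameterError("validation COG set is empty")
    if ladder is None:
        ladder = default_threshold_ladder()
    ladder = list(ladder)
    if any(not 0 <= t <= 999 for t in ladder):
        raise ParameterError("ladder values outside [0, 999]")
    rows: list[ThresholdRow] = []
    prev_cogs: int | None = None
    selected: int | None = None
    for threshold in ladder:
        modules, _, _ = run_on_cohort(
            networks,
            annotations,
            None,
            edge_threshold=threshold,
            pairs=pairs,
            p_threshold=p_threshold,
            bound_mode=bound_mode,
            min_cogs=min_cogs,
        )
        found = set().union(*(m.cog_set for m in modules)) if modules else set()
        accuracy = len(validation & found) / len(validation)
        unique = len(found)
        rows.append(
            ThresholdRow(
                threshold=threshold,
                accuracy=accuracy,
                n_modules=len(modules),
                unique_cogs=unique,
                delta_cogs=0 if prev_cogs is None else unique - prev_cogs,
            )
        )
        prev_cogs = unique
        if selected is None and accuracy >= accuracy_target:
            selected = threshold
            break  # first qualifying threshold on the descending ladder
    if selected is not None:
        return ThresholdReport(selected=selected, target_reached=True, rows=rows)
    best = max(rows, key=lambda r: (r.accuracy, r.threshold))
    logger.warning(
        "no ladder value reached accuracy %.2f; falling back to %d "
        "(accuracy %.2f)",
        accuracy_target,
        best.threshold,
        best.accuracy,
    )
    return ThresholdReport(selected=best.threshold, target_reached=False, rows=rows)


# ---------------------------------------------------------------------------
# subsampling robustness
# ---------------------------------------------------------------------------


@dataclass
class RobustnessReport:
    trials: list[dict]
    overlap: np.ndarray  # pairwise overlap of top-k COG-set lists
    mean_overlap: float


def _rank_key(module: ModuleClique):
    s_p = module.phylo_score if module.phylo_score is not None else 0.0
    return (module.p_value, -s_p, module.canonical_key())


def subsample_robustness(
    networks: Sequence[FunctionalAssociationNetwork],
    annotations: Sequence[OrganismAnnotation],
    dm: PhyloDistanceMatrix | None,
    grouping: Mapping[str, str],
    n_trials: int,
    subset_size_range: tuple[int, int],
    seed: int,
    *,
    edge_threshold: int = 700,
    pairs: Sequence[tuple[int, int]] | None = None,
    p_threshold: float = 0.005,
    min_cogs: int = 1,
    top_k: int = 10,
) -> RobustnessReport:
    """Stability of the top-ranked modules under genus-grouped subsampling.

    Each trial samples one organism per group, then a random subset whose
    size is drawn from ``subset_size_range``, reruns the pipeline on that
    sub-cohort and ranks modules by (p-value, then phylogenetic score). The
    report gives, for every trial pair, the overlap fraction of their top-k
    COG-set lists.
    """
    by_id = {n.organism_id: n for n in networks}
    ann_by_id = {a.organism_id: a for a in annotations}
    missing = set(grouping) - set(by_id)
    if missing:
        raise InputError(f"grouped organisms without networks: {sorted(missing)}")
    positives = {
        a.organism_id
        for a in annotations
        if a.phenotype is Phenotype.POSITIVE
    }
    if not positives <= set(grouping):
        raise ParameterError("grouping must cover every positive organism")
    groups: dict[str, list[str]] = {}
    for org, gid in grouping.items():
        groups.setdefault(gid, []).append(org)
    lo, hi = subset_size_range
    if lo > len(groups):
        raise ParameterError(
            f"minimum subset size {lo} exceeds number of groups {len(groups)}"
        )
    if lo < 1 or lo > hi:
        raise ParameterError("invalid subset_size_range")

    trials: list[dict] = []
    top_lists: list[list[frozenset[str]]] = []
    for trial in range(n_trials):
        rng = np.random.default_rng(
            np.random.SeedSequence(seed, spawn_key=(trial,))
        )
        chosen = None
        for _ in range(100):  # retry until >= 1 positive lands in the subset
            reps = [
                members[rng.integers(len(members))]
                for members in (sorted(groups[g]) for g in sorted(groups))
            ]
            size = int(rng.integers(lo, min(hi, len(reps)) + 1))
            idx = rng.choice(len(reps), size=size, replace=False)
            candidate = sorted(reps[i] for i in idx)
            if any(o in positives for o in candidate):
                chosen = candidate
                break
        if chosen is None:
            raise ParameterError(
                "could not draw a subset containing a positive organism"
            )
        sub_nets = [by_id[o] for o in chosen]
        sub_anns = [ann_by_id[o] for o in chosen]
        modules, selected, _ = run_on_cohort(
            sub_nets,
            sub_anns,
            dm,
            edge_threshold=edge_threshold,
            pairs=pairs,
            p_threshold=p_threshold,
            min_cogs=min_cogs,
        )
        ranked = sorted(modules, key=_rank_key)
        top = [m.cog_set for m in ranked[:top_k]]
        top_lists.append(top)
        trials.append(
            {
                "organisms": chosen,
                "n_modules": len(modules),
                "pairs": [(p.alpha, p.beta) for p in selected],
                "top_modules": [sorted(c) for c in top],
            }
        )

    n = len(top_lists)
    overlap = np.ones((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            a, b = set(top_lists[i]), set(top_lists[j])
            if not a and not b:
                frac = 1.0
            elif not a or not b:
                frac = 0.0
            else:
                frac = len(a & b) / min(len(a), len(b))
            overlap[i, j] = overlap[j, i] = frac
    off_diag = overlap[np.triu_indices(n, k=1)]
    mean = float(off_diag.mean()) if off_diag.size else 1.0
    return RobustnessReport(trials=trials, overlap=overlap, mean_overlap=mean)
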