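"""Supertype-partitioned RLS ensemble with isotype routing.

Rather than one regressor over all binding data, the training set is
split by the supertype assignment of each record's molecule — four
main supertypes plus the diverse pool — and a separate kernel RLS
model is fitted per cluster.  Prediction for a molecule that belongs
to a cluster uses that cluster's model alone.  For a molecule unseen
at clustering time, the models of its isotype are combined by uniform
averaging:

* unseen DR  -> mean of mainDR and diverse (the diverse pool is
  predominantly DR data);
* unseen DP  -> mainDP alone;
* unseen DQ  -> mean of mainDQ1 and mainDQ2.

The routing table is fixed at train time (and user-overridable); it
degrades gracefully when a routed cluster is empty.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .clustering import DIVERSE_LABEL, SupertypeAssignment
from .io import BindingDataset, BindingRecord, parse_allele_name
from .kernel import KernelEngine, KernelParams
from .rls import DEFAULT_LAMBDA, RLSModel, fit as rls_fit

log = logging.getLogger(__name__)

ISOTYPES = ("DR", "DP", "DQ")

Query = tuple[str, str, str, str]  # (allele_name, alpha, beta, peptide)


class RoutingError(ValueError):
    pass


def default_routing(labels: list[str]) -> dict[str, list[str]]:
    """Build the isotype routing table from the available cluster labels.

    DR routes to the main DR cluster(s) plus diverse; DP to the main
    DP cluster(s) only; DQ to all main DQ clusters.  If an isotype has
    no main cluster the diverse model stands in; if a routed cluster
    is missing it is simply dropped (logged).  An isotype with nothing
    to route to falls back to every available model.
    """
    routing: dict[str, list[str]] = {}
    has_diverse = DIVERSE_LABEL in labels
    for isotype in ISOTYPES:
        route = sorted(l for l in labels if l.startswith(f"main{isotype}"))
        if isotype == "DR" and has_diverse:
            route.append(DIVERSE_LABEL)
        if not route:
            route = [DIVERSE_LABEL] if has_diverse else sorted(labels)
            log.warning(
                "no main %s cluster available; routing unseen %s alleles "
                "to %s", isotype, isotype, route,
            )
        routing[isotype] = route
    return routing


@dataclass
class SuperMHCModel:
    """One RLS base learner per cluster plus the isotype routing table."""

    cluster_models: dict[str, RLSModel]
    assignment: SupertypeAssignment
    routing: dict[str, list[str]]
    params: KernelParams
    lam: float

    def save(self, path: str | Path) -> None:
        payload = {
            "cluster_models": {lab: m.to_dict()
                               for lab, m in self.cluster_models.items()},
            "assignment": self.assignment.to_dict(),
            "routing": self.routing,
            "params": self.params.to_dict(),
            "lam": repr(self.lam),
        }
        Path(path).write_text(json.dumps(payload, indent=1, sort_keys=True))

    @classmethod
    def load(cls, path: str | Path) -> "SuperMHCModel":
        d = json.loads(Path(path).read_text())
        return cls(
            cluster_models={lab: RLSModel.from_dict(md)
                            for lab, md in d["cluster_models"].items()},
            assignment=SupertypeAssignment.from_dict(d["assignment"]),
            routing={k: list(v) for k, v in d["routing"].items()},
            params=KernelParams.from_dict(d["params"]),
            lam=float(d["lam"]),
        )


def partition_training(dataset: BindingDataset,
                       assignment: SupertypeAssignment
                       ) -> dict[str, list[BindingRecord]]:
    """Split records by their molecule's cluster label.

    Molecules absent from the assignment are routed to the diverse
    cluster with a warning.  The split is disjoint and exhaustive.
    """
    parts: dict[str, list[BindingRecord]] = {}
    unassigned: set[str] = set()
    for rec in dataset.records:
        label = assignment.labels.get(rec.allele_name)
        if label is None:
            unassigned.add(rec.allele_name)
            label = DIVERSE_LABEL
        parts.setdefault(label, []).append(rec)
    if unassigned:
        log.warning("%d molecules missing from the supertype assignment "
                    "were routed to the diverse cluster: %s",
                    len(unassigned), sorted(unassigned))
    for label, recs in sorted(parts.items()):
        log.info("cluster %s: %d training records", label, len(recs))
    return parts


def train(dataset: BindingDataset, assignment: SupertypeAssignment,
          params: KernelParams | None = None, lam: float = DEFAULT_LAMBDA,
          engine: KernelEngine | None = None,
          routing: dict[str, list[str]] | None = None) -> SuperMHCModel:
    """Fit one RLS model per non-empty cluster and fix the routing table."""
    params = params or KernelParams()
    engine = engine or KernelEngine(params)
    dataset.validate()
    parts = partition_training(dataset, assignment)
    if not parts:
        raise ValueError("no training clusters: the dataset is empty")
    cluster_models: dict[str, RLSModel] = {}
    for label in sorted(parts):
        recs = parts[label]
        points = [
            (dataset.catalog[r.allele_name].alpha_region,
             dataset.catalog[r.allele_name].beta_region,
             r.peptide)
            for r in recs
        ]
        targets = [r.affinity for r in recs]
        cluster_models[label] = rls_fit(points, targets, params, lam,
                                        engine=engine)
    if routing is None:
        routing = default_routing(sorted(cluster_models))
    return SuperMHCModel(cluster_models=cluster_models,
                         assignment=assignment, routing=routing,
                         params=params, lam=lam)


def predict(model: SuperMHCModel, queries: list[Query],
            engine: KernelEngine | None = None,
            clip: bool = False) -> tuple[np.ndarray, list[list[str]]]:
    """Route each query and return (affinities, per-query provenance).

    A query whose molecule belongs to a cluster with a model is scored
    by that single model; otherwise the models routed for its isotype
    are averaged with equal weights.  Provenance lists which cluster
    models fired for each query.
    """
    engine = engine or KernelEngine(model.params)
    groups: dict[tuple[str, ...], list[int]] = {}
    provenance: list[list[str] | None] = [None] * len(queries)
    for qi, (allele_name, _, _, _) in enumerate(queries):
        label = model.assignment.labels.get(allele_name)
        if label is not None and label in model.cluster_models:
            used = (label,)
        else:
            isotype = parse_allele_name(allele_name).isotype
            if isotype not in model.routing:
                raise RoutingError(
                    f"no routing rule for isotype {isotype!r}"
                )
            used = tuple(l for l in model.routing[isotype]
                         if l in model.cluster_models)
            if not used:
                raise RoutingError(
                    f"no trained model available to route a {isotype} query"
                )
        groups.setdefault(used, []).append(qi)
        provenance[qi] = list(used)

    out = np.empty(len(queries))
    for used, idxs in groups.items():
        triples = [queries[qi][1:] for qi in idxs]
        preds = np.mean(
            [model.cluster_models[lab].predict(triples, engine=engine)
             for lab in used],
            axis=0,
        )
        out[idxs] = preds
    if clip:
        out = np.clip(out, 0.0, 1.0)
    return out, provenance


def queries_from_dataset(dataset: BindingDataset) -> list[Query]:
    """(allele, alpha, beta, peptide) queries for every record."""
    dataset.validate()
    return [
        (r.allele_name,
         dataset.catalog[r.allele_name].alpha_region,
         dataset.catalog[r.allele_name].beta_region,
         r.peptide)
        for r in dataset.records
    ]
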