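"""Contaminant exclusion and four-way protein categorisation.

A protein recovered from adhesive material is excluded as presumed cellular
contamination when it carries an intracellular annotation without a signal
peptide, or when it is an ER-resident protein (signal peptide plus a
C-terminal HDEL/KDEL retention motif).  Every retained protein is then
assigned exactly one category:

1. **bulk** — no homologue outside thoracican barnacles (taxonomic
   uniqueness wins over any domain tag);
2. **pheromone** — carries an alpha-macroglobulin (SIPC/MULTIFUNCin-like)
   or cupin (waterborne settlement pheromone) domain tag;
3. **enzyme_or_inhibitor** — carries an enzyme or protease-inhibitor family
   tag (inhibitors are counted with enzymes);
4. **homologous** — everything else with outgroup homology, keyed by a
   known family tag when present.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import pandas as pd
import yaml

from cementome.seqio import AnnotationRow, SequenceRecord

logger = logging.getLogger(__name__)

CATEGORIES = ("cellular_excluded", "bulk", "pheromone", "enzyme_or_inhibitor", "homologous")

#: decision order for domain-tag categories (after the bulk test)
_TAG_CATEGORY_ORDER = ("pheromone", "enzyme_or_inhibitor", "homologous")

ER_MOTIF_RE = re.compile(r"[HK]DEL$")

_PF_SHORT_RE = re.compile(r"^pf(\d{5})$")


def normalize_tag(tag: str) -> str:
    """Lowercase a domain tag and expand the short Pfam form (PF00095 -> pfam00095)."""
    tag = str(tag).strip().lower()
    short = _PF_SHORT_RE.match(tag)
    return f"pfam{short.group(1)}" if short else tag


@dataclass(frozen=True)
class Category:
    """Category assignment for one protein; ``subtype`` is the family key
    for pheromone / enzyme / homologous proteins."""

    value: str
    subtype: str | None = None

    def __post_init__(self) -> None:
        if self.value not in CATEGORIES:
            raise ValueError(f"unknown category {self.value!r}")
        if self.subtype is not None and self.value in ("bulk", "cellular_excluded"):
            raise ValueError(f"category {self.value!r} takes no subtype")


class DomainCatalog:
    """Mapping from conserved-domain tag to (category, family key).

    Seeded from the packaged defaults (alpha-macroglobulin and cupin
    pheromone domains, the enzyme/protease-inhibitor families, and the
    named homologous-protein families); extensible via :meth:`update` or a
    user YAML of the same layout.  Every tag maps to exactly one pair.
    """

    def __init__(self, mapping: dict[str, tuple[str, str]] | None = None) -> None:
        self._map: dict[str, tuple[str, str]] = dict(mapping or {})

    @classmethod
    def default(cls) -> "DomainCatalog":
        with resources.files("cementome.data").joinpath("domain_catalog.yaml").open() as fh:
            return cls._from_config(yaml.safe_load(fh))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "DomainCatalog":
        with open(path) as fh:
            return cls._from_config(yaml.safe_load(fh))

    @classmethod
    def _from_config(cls, cfg: dict) -> "DomainCatalog":
        mapping: dict[str, tuple[str, str]] = {}
        for category, families in cfg.items():
            if category not in _TAG_CATEGORY_ORDER:
                raise ValueError(f"unknown catalog category {category!r}")
            for family, tags in families.items():
                for tag in tags:
                    tag = normalize_tag(tag)
                    if tag in mapping and mapping[tag] != (category, family):
                        raise ValueError(
                            f"domain tag {tag!r} maps to both {mapping[tag]} and {(category, family)}"
                        )
                    mapping[tag] = (category, str(family))
        return cls(mapping)

    def update(self, extra: dict[str, tuple[str, str]]) -> None:
        for tag, pair in extra.items():
            self._map[normalize_tag(tag)] = (pair[0], str(pair[1]))

    def lookup(self, tag: str) -> tuple[str, str] | None:
        return self._map.get(normalize_tag(tag))

    def __len__(self) -> int:
        return len(self._map)


def has_er_retention_motif(sequence: str) -> bool:
    """C-terminal HDEL/KDEL test, used when the annotation flag is absent.

    The motivating observation names HDEL; KDEL is included as the
    canonical ER-retention variant.
    """
    return bool(ER_MOTIF_RE.search(sequence.upper()))


def filter_contaminants(annotation: AnnotationRow, sequence: SequenceRecord | None = None) -> bool:
    """True when the protein is excluded as a cellular contaminant.

    Exclude iff (intracellular annotation AND no signal peptide) OR
    (signal peptide AND ER-retention motif).  When ``sequence`` is given and
    the annotation's ``er_motif`` flag is False, the motif is recomputed
    from the C-terminus.
    """
    er = annotation.er_motif
    if not er and sequence is not None:
        er = has_er_retention_motif(sequence.sequence)
    return (annotation.intracellular and not annotation.signal_peptide) or (
        annotation.signal_peptide and er
    )


def assign_category(annotation: AnnotationRow, catalog: DomainCatalog | None = None) -> Category:
    """Assign the category of a retained (non-excluded) protein.

    Ordered decision list: no outgroup homologue -> bulk; then the first of
    pheromone / enzyme_or_inhibitor / homologous whose tag set intersects
    the protein's domain tags; otherwise homologous/"unassigned".  Tags
    mapping to different categories are resolved by that order and logged.
    """
    if catalog is None:
        catalog = DomainCatalog.default()
    if not annotation.outgroup_homolog:
        return Category("bulk")
    hits: dict[str, list[str]] = {c: [] for c in _TAG_CATEGORY_ORDER}
    for tag in sorted(annotation.domain_tags):
        pair = catalog.lookup(tag)
        if pair is not None:
            hits[pair[0]].append(pair[1])
    n_categories = sum(1 for fams in hits.values() if fams)
    if n_categories > 1:
        logger.warning(
            "protein %s has domain tags mapping to multiple categories %s; "
            "resolved by pheromone > enzyme > homologous order",
            annotation.accession,
            {c: f for c, f in hits.items() if f},
        )
    for category in _TAG_CATEGORY_ORDER:
        if hits[category]:
            return Category(category, hits[category][0])
    return Category("homologous", "unassigned")


def classify_proteome(
    records: list[SequenceRecord],
    annotations: dict[str, AnnotationRow],
    catalog: DomainCatalog | None = None,
) -> pd.DataFrame:
    """Run exclusion + categorisation over a whole proteome.

    Returns a DataFrame indexed by accession with columns ``category``,
    ``subtype`` and ``excluded``; excluded proteins carry category
    ``cellular_excluded``.
    """
    if catalog is None:
        catalog = DomainCatalog.default()
    rows = []
    for rec in records:
        ann = annotations.get(rec.id)
        if ann is None:
            raise KeyError(f"no annotation row for protein {rec.id!r}")
        if filter_contaminants(ann, rec):
            rows.append({"accession": rec.id, "category": "cellular_excluded", "subtype": "", "excluded": True})
        else:
            cat = assign_category(ann, catalog)
            rows.append({"accession": rec.id, "category": cat.value, "subtype": cat.subtype or "", "excluded": False})
    return pd.DataFrame(rows).set_index("accession")


def category_summary(
    assignments: pd.DataFrame,
    matched_in_adhesive: set[str] | None = None,
    matched_in_genome: set[str] | None = None,
) -> pd.DataFrame:
    """Per-category totals and unique-protein arithmetic (pure set subtraction).

    For each category: ``total`` retained proteins, ``unique_in_adhesive``
    (no match in the other species' adhesive proteome), and
    ``completely_unique`` (additionally no match anywhere in the other
    species' genome).  ``matched_in_genome`` applies only to proteins
    already unique in the adhesive comparison.
    """
    matched_in_adhesive = matched_in_adhesive or set()
    matched_in_genome = matched_in_genome or set()
    retained = assignments[~assignments["excluded"]]
    rows = []
    for category in ("bulk", "pheromone", "enzyme_or_inhibitor", "homologous"):
        members = set(retained.index[retained["category"] == category])
        unique = members - matched_in_adhesive
        completely_unique = unique - matched_in_genome
        rows.append(
            {
                "category": category,
                "total": len(members),
                "unique_in_adhesive": len(unique),
                "completely_unique": len(completely_unique),
            }
        )
    rows.append(
        {
            "category": "cellular_excluded",
            "total": int(assignments["excluded"].sum()),
            "unique_in_adhesive": 0,
            "completely_unique": 0,
        }
    )
    return pd.DataFrame(rows).set_index("category")
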