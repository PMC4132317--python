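"""Panel-vs-proteome survey orchestration.

Runs every query of the panel against every taxon proteome, recording
per cell the best hit, its maximal bit score and E-value, the score
tier, and (optionally) the shuffle-null comparison.  Mirrors the
structure of the published survey tables: maxima below 50 bits render
as "low similarity", scores of 100 and above render bold, and cells
whose shuffle null fails to separate native from analog render italic
("exclusive").  Includes the reverse-search procedure used to
characterize exclusive proteins: ranked hits of one (sub)sequence
against a reference proteome, annotated by whether the aligned region
falls in the subject's C-terminal third.
"""

from __future__ import annotations

import hashlib
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import pandas as pd
import yaml

from .pairwise_align import ScoringScheme, bit_score, default_scheme, encode, evalue, local_align, local_align_score
from .seqio import ProteinRecord, QueryPanel
from .shuffle_null import (
    ALPHA,
    EXCLUSIVITY_MIN_BITS,
    EXCLUSIVITY_RATIO,
    NullComparison,
    SimilarityTier,
    classify_tier,
    null_comparison,
)

logger = logging.getLogger("scsurvey.survey")

LOW_SIMILARITY_BITS = 50.0


@dataclass
class SurveyConfig:
    e_max: float = 100.0
    k: int = 10
    null_model: bool = False
    seed: int = 0
    n_analogs: int = 1
    tier_thresholds: tuple[float, float] = (50.0, 100.0)
    exclusivity_ratio: float = EXCLUSIVITY_RATIO
    alpha: float = ALPHA
    exclusivity_min_bits: float = EXCLUSIVITY_MIN_BITS
    max_targets: int = 1000
    c_term_fraction: float = 1.0 / 3.0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SurveyConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        cfg = cls(**data)
        return cfg

    def to_yaml(self, path: str | Path) -> None:
        data = asdict(self)
        data["tier_thresholds"] = list(self.tier_thresholds)
        Path(path).write_text(yaml.safe_dump(data))


@dataclass
class SurveyCell:
    query_id: str
    taxon: str
    best_hit_id: str | None
    max_bits: float
    evalue: float
    tier: SimilarityTier
    null_cmp: NullComparison | None = None

    @property
    def no_hit(self) -> bool:
        return self.best_hit_id is None


@dataclass
class SurveyTable:
    taxa: list[str]
    query_ids: list[str]
    cells: dict[tuple[str, str], SurveyCell]  # (taxon, query_id) -> cell
    metadata: dict = field(default_factory=dict)

    def cell(self, taxon: str, query_id: str) -> SurveyCell:
        return self.cells[(taxon, query_id)]

    # -- serialization ------------------------------------------------------

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for (taxon, qid), c in sorted(self.cells.items()):
            rows.append(
                {
                    "taxon": taxon,
                    "query_id": qid,
                    "best_hit_id": c.best_hit_id or "",
                    "max_bits": round(c.max_bits, 4),
                    "evalue": c.evalue,
                    "tier": c.tier.name,
                    "exclusive": bool(c.null_cmp.exclusive_flag) if c.null_cmp else False,
                    "native_max": round(c.null_cmp.native_max, 4) if c.null_cmp else "",
                    "random_max": round(c.null_cmp.random_max, 4) if c.null_cmp else "",
                    "p_value": c.null_cmp.p_value if c.null_cmp else "",
                }
            )
        return pd.DataFrame(rows)

    def to_tsv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path: str | Path) -> "SurveyTable":
        df = pd.read_csv(path, sep="\t", keep_default_na=False)
        cells: dict[tuple[str, str], SurveyCell] = {}
        for _, row in df.iterrows():
            null_cmp = None
            if row.get("native_max", "") != "":
                null_cmp = NullComparison(
                    query_id=row["query_id"],
                    native_max=float(row["native_max"]),
                    random_max=float(row["random_max"]),
                    native_top=[float(row["native_max"])],
                    random_top=[float(row["random_max"])],
                    p_value=float(row["p_value"]) if row["p_value"] != "" else None,
                    exclusive_flag=bool(row["exclusive"]),
                )
            cells[(row["taxon"], row["query_id"])] = SurveyCell(
                query_id=row["query_id"],
                taxon=row["taxon"],
                best_hit_id=row["best_hit_id"] or None,
                max_bits=float(row["max_bits"]),
                evalue=float(row["evalue"]),
                tier=SimilarityTier[row["tier"]],
                null_cmp=null_cmp,
            )
        taxa = sorted({t for t, _ in cells})
        qids = sorted({q for _, q in cells})
        return cls(taxa=taxa, query_ids=qids, cells=cells)

    def render_markdown(self, low_cutoff: float = LOW_SIMILARITY_BITS, bold_cutoff: float = 100.0) -> str:
        """Published-style grid: one row per taxon, scores in
        parentheses, bold >= 100 bits, italic for exclusives, maxima
        below the cutoff shown as 'low similarity'."""
        lines = ["| taxon | " + " | ".join(self.query_ids) + " |",
                 "|" + "---|" * (len(self.query_ids) + 1)]
        for taxon in self.taxa:
            rendered = []
            for qid in self.query_ids:
                c = self.cells[(taxon, qid)]
                if c.no_hit or c.max_bits < low_cutoff:
                    rendered.append("low similarity")
                    continue
                text = f"{qid} ({c.max_bits:.0f})"
                if c.max_bits >= bold_cutoff:
                    text = f"**{text}**"
                if c.null_cmp is not None and c.null_cmp.exclusive_flag:
                    text = f"*{text}*"
                rendered.append(text)
            lines.append(f"| {taxon} | " + " | ".join(rendered) + " |")
        return "\n".join(lines)


# ---------------------------------------------------------------------------
# Survey
# ---------------------------------------------------------------------------

def _cell_key(query: ProteinRecord, proteome: list[ProteinRecord], scheme: ScoringScheme) -> str:
    h = hashlib.sha1()
    h.update(query.seq.encode())
    for rec in proteome:
        h.update(b"\0" + rec.id.encode() + b"\0" + rec.seq.encode())
    h.update(f"{scheme.name}|{scheme.gap_open}|{scheme.gap_extend}|{scheme.lam}|{scheme.K}".encode())
    return h.hexdigest()


def survey_cell(
    query: ProteinRecord,
    taxon: str,
    proteome: list[ProteinRecord],
    scheme: ScoringScheme,
    cfg: SurveyConfig,
) -> SurveyCell:
    """One (query, taxon) cell: maximal bit score, best hit, E-value,
    tier, optional shuffle-null comparison."""
    n_db = sum(len(r.seq) for r in proteome)
    q_enc = encode(query.seq)
    best_raw = -1
    best_rec: ProteinRecord | None = None
    for rec in sorted(proteome, key=lambda r: r.id):  # deterministic under ties
        raw = local_align_score(q_enc, encode(rec.seq), scheme)
        if raw > best_raw:
            best_raw = raw
            best_rec = rec
    bits = bit_score(best_raw, scheme)
    ev = evalue(bits, len(query.seq), n_db)
    if ev > cfg.e_max:
        cell = SurveyCell(query_id=query.id, taxon=taxon, best_hit_id=None,
                          max_bits=0.0, evalue=ev,
                          tier=classify_tier(0.0, cfg.tier_thresholds))
    else:
        assert best_rec is not None
        res = local_align(query, best_rec, scheme, m=len(query.seq), n=n_db)
        cell = SurveyCell(query_id=query.id, taxon=taxon, best_hit_id=best_rec.id,
                          max_bits=res.bit_score, evalue=res.evalue,
                          tier=classify_tier(res.bit_score, cfg.tier_thresholds))
    if cfg.null_model:
        # stable per-cell seed (process-independent, < 2**31)
        digest = hashlib.sha1(f"{query.id}|{taxon}".encode()).hexdigest()
        cell_seed = (cfg.seed + int(digest[:8], 16)) % (2**31 - 1)
        cell.null_cmp = null_comparison(
            query, proteome, scheme,
            seed=cell_seed,
            k=cfg.k, e_max=cfg.e_max, n_analogs=cfg.n_analogs,
            exclusivity_ratio=cfg.exclusivity_ratio, alpha=cfg.alpha,
            min_bits=cfg.exclusivity_min_bits,
        )
    logger.info(
        "cell %s x %s: best=%s bits=%.1f tier=%s",
        query.id, taxon, cell.best_hit_id, cell.max_bits, cell.tier.name,
    )
    return cell


def survey(
    panel: QueryPanel | list[ProteinRecord],
    proteomes: dict[str, list[ProteinRecord]],
    scheme: ScoringScheme | None = None,
    cfg: SurveyConfig | None = None,
    cache: dict | None = None,
) -> SurveyTable:
    """Scan every panel query against every taxon proteome.

    ``panel`` is either a resolved :class:`QueryPanel` or a plain list
    of query records.  ``cache`` (optional dict) memoizes cells by a
    content hash of query + proteome + scheme so interrupted surveys
    can resume.
    """
    if scheme is None:
        scheme = default_scheme()
    if cfg is None:
        cfg = SurveyConfig()
    queries = panel.query_records() if isinstance(panel, QueryPanel) else panel
    for taxon, prot in proteomes.items():
        if not prot:
            raise ValueError(f"proteome {taxon!r} is empty")
    cells: dict[tuple[str, str], SurveyCell] = {}
    for query in queries:
        for taxon, prot in proteomes.items():
            key = _cell_key(query, prot, scheme) if cache is not None else None
            if key is not None and key in cache:
                cells[(taxon, query.id)] = cache[key]
                continue
            cell = survey_cell(query, taxon, prot, scheme, cfg)
            cells[(taxon, query.id)] = cell
            if key is not None:
                cache[key] = cell
    return SurveyTable(
        taxa=list(proteomes.keys()),
        query_ids=[q.id for q in queries],
        cells=cells,
        metadata={
            "scheme": scheme.name,
            "gap_open": scheme.gap_open,
            "gap_extend": scheme.gap_extend,
            "e_max": cfg.e_max,
            "seed": cfg.seed,
            "null_model": cfg.null_model,
        },
    )


def reverse_search(
    subject: ProteinRecord,
    reference_proteome: list[ProteinRecord],
    scheme: ScoringScheme | None = None,
    region: tuple[int, int] | None = None,
    cfg: SurveyConfig | None = None,
) -> list[tuple[SurveyCell, bool]]:
    """Ranked hits of ``subject`` (or its sub-region) against a
    reference proteome.

    Each hit is paired with a flag: does its aligned span on the
    subject overlap the subject's C-terminal third (fraction
    configurable)?  Used to show that exclusive-protein similarity is
    confined to the coiled-coil tail.
    """
    if scheme is None:
        scheme = default_scheme()
    if cfg is None:
        cfg = SurveyConfig()
    if not reference_proteome:
        return []
    offset = 0
    probe = subject
    if region is not None:
        start, end = region
        if not (0 <= start < end <= len(subject.seq)):
            raise ValueError(f"region {region} out of bounds for {subject.id}")
        probe = ProteinRecord(id=subject.id, seq=subject.seq[start:end],
                              description=subject.description, taxon=subject.taxon)
        offset = start
    n_db = sum(len(r.seq) for r in reference_proteome)
    c_term_start = len(subject.seq) * (1.0 - cfg.c_term_fraction)
    hits: list[tuple[SurveyCell, bool]] = []
    for rec in sorted(reference_proteome, key=lambda r: r.id):
        res = local_align(probe, rec, scheme, m=len(probe.seq), n=n_db)
        if res.raw_score <= 0 or res.evalue > cfg.e_max:
            continue
        span_on_subject = (offset + res.q_span[0], offset + res.q_span[1])
        overlaps_cterm = span_on_subject[1] > c_term_start
        cell = SurveyCell(query_id=subject.id, taxon=rec.taxon or "reference",
                          best_hit_id=rec.id, max_bits=res.bit_score,
                          evalue=res.evalue,
                          tier=classify_tier(res.bit_score, cfg.tier_thresholds))
        hits.append((cell, overlaps_cterm))
    hits.sort(key=lambda t: (-t[0].max_bits, t[0].best_hit_id))
    return hits[: cfg.max_targets]


def flag_exclusives(table: SurveyTable) -> list[tuple[str, str]]:
    """(taxon, query_id) pairs whose shuffle-null comparison flagged the
    cell exclusive; cells lacking a null comparison are skipped with a
    logged warning."""
    flagged: list[tuple[str, str]] = []
    for (taxon, qid), cell in sorted(table.cells.items()):
        if cell.null_cmp is None:
            logger.warning("cell %s x %s has no null comparison; skipped", qid, taxon)
            continue
        if cell.null_cmp.exclusive_flag:
            flagged.append((taxon, qid))
    return flagged
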