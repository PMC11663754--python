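"""File formats: answer logs (JSONL), value systems, score matrices, manifests.

Every writer has a matching reader and round-trips without loss; the
formats are all plain text (CSV / JSON / JSON-lines) so that runs are
diffable and reproducible from the manifest alone.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd

from .paprika import RespondentSession, ValueSystem, Verdict
from .scheme import CriterionScheme
from .scoring import ScoreMatrix


# ---------------------------------------------------------------------------
# Answer logs
# ---------------------------------------------------------------------------


def answer_records(respondent_id: str, session: RespondentSession) -> list[dict]:
    """Serialise a session's answers: one record per trade-off answer.

    Levels a1/a2 (and b1/b2) are the first and second alternative's
    levels on each active criterion.
    """
    records = []
    for qi, ans in enumerate(session.answers):
        q = ans.question
        a, b = q.active_criteria
        records.append(
            {
                "respondent_id": respondent_id,
                "question_index": qi,
                "criterion_a": a,
                "level_a1": q.first.levels[a],
                "level_a2": q.second.levels[a],
                "criterion_b": b,
                "level_b1": q.first.levels[b],
                "level_b2": q.second.levels[b],
                "verdict": ans.verdict.value,
            }
        )
    return records


def write_answer_log(path, sessions: dict[str, RespondentSession]) -> None:
    with open(path, "w") as fh:
        for rid, session in sessions.items():
            for rec in answer_records(rid, session):
                fh.write(json.dumps(rec) + "\n")


def read_answer_log(path) -> dict[str, list[dict]]:
    logs: dict[str, list[dict]] = {}
    with open(path) as fh:
        for line in fh:
            if not line.strip():
                continue
            rec = json.loads(line)
            logs.setdefault(rec["respondent_id"], []).append(rec)
    for recs in logs.values():
        recs.sort(key=lambda r: r["question_index"])
    return logs


def replay_answers(scheme: CriterionScheme, records: list[dict]) -> RespondentSession:
    """Rebuild a session from its answer log.

    The engine's question order is deterministic given the scheme and
    the answers, so replaying the verdicts reproduces the session;
    each record is checked against the question actually issued.
    """
    session = RespondentSession(scheme)
    for rec in records:
        q = session.next_question()
        if q is None:
            raise ValueError("answer log longer than the session")
        a, b = q.active_criteria
        expected = (
            rec["criterion_a"],
            rec["level_a1"],
            rec["level_a2"],
            rec["criterion_b"],
            rec["level_b1"],
            rec["level_b2"],
        )
        got = (
            a,
            q.first.levels[a],
            q.second.levels[a],
            b,
            q.first.levels[b],
            q.second.levels[b],
        )
        if expected != got:
            raise ValueError(
                f"answer log mismatch at question {rec['question_index']}: "
                f"log has {expected}, engine asked {got}"
            )
        session.record_answer(Verdict(rec["verdict"]))
    session.next_question()  # advance status if exhausted
    return session


# ---------------------------------------------------------------------------
# Value systems
# ---------------------------------------------------------------------------


def value_systems_to_csv(path, systems: dict[str, ValueSystem]) -> None:
    """Long CSV: respondent_id, criterion, level, value."""
    frames = []
    for rid, vs in systems.items():
        df = vs.to_frame()
        df.insert(0, "respondent_id", rid)
        frames.append(df)
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)


def value_systems_from_csv(path, scheme: CriterionScheme) -> dict[str, ValueSystem]:
    df = pd.read_csv(path, dtype={"respondent_id": str})
    out: dict[str, ValueSystem] = {}
    for rid, sub in df.groupby("respondent_id", sort=False):
        values = np.zeros((scheme.n_criteria, scheme.n_levels))
        for _, row in sub.iterrows():
            ci = scheme.criterion_index(row["criterion"])
            values[ci, int(row["level"]) - 1] = row["value"]
        out[str(rid)] = ValueSystem(scheme=scheme, values=values)
    return out


def value_system_to_json(vs: ValueSystem) -> dict:
    return {
        "criteria": list(vs.scheme.criteria),
        "levels": vs.scheme.n_levels,
        "values": vs.values.tolist(),
        "weights": vs.weights.tolist(),
        "consistent": vs.consistent,
    }


# ---------------------------------------------------------------------------
# Score matrices (long format, multi-region)
# ---------------------------------------------------------------------------


def score_matrices_to_csv(path, matrices: dict[str, ScoreMatrix]) -> None:
    """Long CSV with region column; cell = level and provenance columns."""
    rows = []
    for region, m in matrices.items():
        for pi, p in enumerate(m.pathogens):
            for ci, c in enumerate(m.scheme.criteria):
                rows.append(
                    {
                        "region": region,
                        "pathogen": p,
                        "criterion": c,
                        "level": int(m.levels[pi, ci]),
                        "provenance": m.provenance[pi, ci],
                    }
                )
    pd.DataFrame(rows).to_csv(path, index=False)


def score_matrices_from_csv(path, scheme: CriterionScheme) -> dict[str, ScoreMatrix]:
    df = pd.read_csv(path)
    out: dict[str, ScoreMatrix] = {}
    for region, sub in df.groupby("region", sort=False):
        pathogens = list(dict.fromkeys(sub["pathogen"]))
        levels = np.zeros((len(pathogens), scheme.n_criteria), dtype=int)
        prov = np.full(levels.shape, "regional_data", dtype=object)
        pidx = {p: i for i, p in enumerate(pathogens)}
        for _, row in sub.iterrows():
            pi = pidx[row["pathogen"]]
            ci = scheme.criterion_index(row["criterion"])
            levels[pi, ci] = int(row["level"])
            prov[pi, ci] = row["provenance"]
        out[str(region)] = ScoreMatrix(
            region=str(region),
            pathogens=pathogens,
            scheme=scheme,
            levels=levels,
            provenance=prov,
        )
    return out


# ---------------------------------------------------------------------------
# Manifests
# ---------------------------------------------------------------------------


def config_hash(obj) -> str:
    """Stable hash of a JSON-serialisable configuration."""
    blob = json.dumps(obj, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


def write_manifest(path, manifest: dict) -> None:
    Path(path).write_text(json.dumps(manifest, indent=2, default=str) + "\n")
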