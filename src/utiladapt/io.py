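"""Trial-table and configuration I/O.

Trial CSV schema (one row per trial, UTF-8, comma-separated, '.' decimal,
header required; ml quantities carry 6 decimals; safe options leave m2/p2
empty):

    session_id, day_index, distribution,
    left_m1, left_p1, left_m2, left_p2,
    right_m1, right_p1, right_m2, right_p2,
    chosen, sequence_tag

Files may start with ``#``-prefixed comment lines (used to record the config
hash and seed that produced them).
"""

from __future__ import annotations

import logging
from pathlib import Path

import pandas as pd

from .distributions import RewardOption
from .trials import ChoiceTrial

__all__ = [
    "read_trials",
    "write_trials",
    "trials_to_frame",
    "TrialParseError",
    "write_fits",
    "read_fits",
]

logger = logging.getLogger("utiladapt")

_COLUMNS = [
    "session_id",
    "day_index",
    "distribution",
    "left_m1",
    "left_p1",
    "left_m2",
    "left_p2",
    "right_m1",
    "right_p1",
    "right_m2",
    "right_p2",
    "chosen",
    "sequence_tag",
]


class TrialParseError(ValueError):
    """A trial file violates the schema; the message lists offending rows."""


def _option_to_cols(opt: RewardOption) -> list:
    row = []
    for i in range(2):
        if i < len(opt.outcomes):
            m, p = opt.outcomes[i]
            row += [round(m, 6), round(p, 6)]
        else:
            row += [None, None]
    return row


def trials_to_frame(trials: list[ChoiceTrial]) -> pd.DataFrame:
    rows = []
    for t in trials:
        rows.append(
            [t.session_id, t.day_index, t.distribution]
            + _option_to_cols(t.left)
            + _option_to_cols(t.right)
            + [t.chosen, t.sequence_tag]
        )
    return pd.DataFrame(rows, columns=_COLUMNS)


def write_trials(trials: list[ChoiceTrial], path, header_comment: str | None = None) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w", encoding="utf-8") as fh:
        if header_comment:
            fh.write(f"# {header_comment}\n")
        trials_to_frame(trials).to_csv(fh, index=False, float_format="%.6f")


def _row_option(row, side: str, idx: int, errors: list[str]) -> RewardOption | None:
    m1, p1 = row[f"{side}_m1"], row[f"{side}_p1"]
    m2, p2 = row[f"{side}_m2"], row[f"{side}_p2"]
    if pd.isna(m1) or pd.isna(p1):
        errors.append(f"row {idx}: missing {side}_m1/{side}_p1")
        return None
    outcomes = [(float(m1), float(p1))]
    if not (pd.isna(m2) and pd.isna(p2)):
        outcomes.append((float(m2), float(p2)))
    total = sum(p for _, p in outcomes)
    if abs(total - 1.0) > 1e-6:
        errors.append(f"row {idx}: {side} probabilities sum to {total}, not 1")
        return None
    try:
        return RewardOption(tuple(outcomes))
    except ValueError as err:
        errors.append(f"row {idx}: {err}")
        return None


def read_trials(path) -> list[ChoiceTrial]:
    """Read and validate a trial CSV; malformed rows raise with row indices."""
    df = pd.read_csv(path, comment="#")
    missing = [c for c in _COLUMNS if c not in df.columns]
    if missing:
        raise TrialParseError(f"missing columns: {missing}")
    if df.empty:
        logger.warning("trial file %s contains a header but no rows", path)
        return []
    errors: list[str] = []
    trials: list[ChoiceTrial] = []
    for idx, row in df.iterrows():
        left = _row_option(row, "left", idx, errors)
        right = _row_option(row, "right", idx, errors)
        if left is None or right is None:
            continue
        try:
            trials.append(
                ChoiceTrial(
                    session_id=str(row["session_id"]),
                    day_index=int(row["day_index"]),
                    distribution=str(row["distribution"]),
                    left=left,
                    right=right,
                    chosen=str(row["chosen"]),
                    sequence_tag=str(row["sequence_tag"]),
                )
            )
        except ValueError as err:
            errors.append(f"row {idx}: {err}")
    if errors:
        raise TrialParseError("; ".join(errors[:20]))
    return trials


def write_fits(records: list[tuple[int, str, "DCMFit"]], path, meta: str | None = None) -> None:
    """Write (day_index, distribution_label, DCMFit) records as JSON lines."""
    import json

    from .dcm import DCMFit  # noqa: F401  (local import avoids a cycle)

    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w", encoding="utf-8") as fh:
        if meta:
            fh.write(json.dumps({"_meta": meta}) + "\n")
        for day, label, fit in records:
            fh.write(
                json.dumps(
                    {
                        "day_index": day,
                        "distribution": label,
                        "family": fit.family,
                        "params": list(fit.params.utility.params),
                        "temperature": fit.params.temperature,
                        "side_bias": fit.params.side_bias,
                        "neg_ll": fit.neg_ll,
                        "n_trials": fit.n_trials,
                        "k": fit.k,
                        "bic": fit.bic,
                        "cv_negll": fit.cv_negll,
                        "converged": fit.converged,
                        "excluded_reason": fit.excluded_reason,
                    }
                )
                + "\n"
            )


def read_fits(path) -> list[tuple[int, str, "DCMFit"]]:
    """Inverse of :func:`write_fits`."""
    import json

    from .dcm import DCMFit, DCMParams
    from .models import UtilityCurve

    out = []
    for line in Path(path).read_text(encoding="utf-8").splitlines():
        rec = json.loads(line)
        if "_meta" in rec:
            continue
        fit = DCMFit(
            params=DCMParams(
                utility=UtilityCurve(rec["family"], tuple(rec["params"])),
                temperature=rec["temperature"],
                side_bias=rec["side_bias"],
            ),
            neg_ll=rec["neg_ll"],
            n_trials=rec["n_trials"],
            k=rec["k"],
            bic=rec["bic"],
            cv_negll=rec["cv_negll"],
            converged=rec["converged"],
            excluded_reason=rec["excluded_reason"],
        )
        out.append((rec["day_index"], rec["distribution"], fit))
    return out
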