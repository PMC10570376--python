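"""Bridge to R lme4 for the binomial cloglog mixed model.

`glmer` is run through an `Rscript` subprocess on a temporary CSV; the
coefficient table, variance components, singularity flag and convergence
messages come back as JSON.  The bridge is deterministic (Laplace
approximation, bobyqa optimizer, no RNG involved).
"""

from __future__ import annotations

import json
import subprocess
import tempfile
from pathlib import Path

__all__ = ["lme4_available", "fit_glmer"]

_R_SCRIPT = r"""
suppressMessages({
  library(lme4)
  library(jsonlite)
})
args <- commandArgs(trailingOnly = TRUE)
d <- read.csv(args[1], stringsAsFactors = FALSE)
d$species <- factor(d$species)
d$region_id <- factor(d$region_id)
form <- as.formula(readLines(args[2], warn = FALSE)[1])
res <- tryCatch({
  m <- glmer(form, data = d, family = binomial(link = "cloglog"),
             control = glmerControl(optimizer = "bobyqa",
                                    calc.derivs = FALSE))
  co <- summary(m)$coefficients
  vc <- as.data.frame(VarCorr(m))
  msgs <- unlist(m@optinfo$conv$lme4$messages)
  if (is.null(msgs)) msgs <- character(0)
  list(ok = TRUE,
       terms = rownames(co),
       estimate = unname(co[, 1]),
       se = unname(co[, 2]),
       z = unname(co[, 3]),
       p = unname(co[, 4]),
       vc_group = vc$grp,
       vc_term = ifelse(is.na(vc$var1), "", vc$var1),
       vc_sd = vc$sdcor,
       singular = isSingular(m),
       messages = msgs)
}, error = function(e) list(ok = FALSE, error = conditionMessage(e)))
writeLines(toJSON(res, auto_unbox = TRUE, digits = 16), args[3])
"""


def lme4_available() -> bool:
    """True when `Rscript` with lme4 + jsonlite can be launched."""
    try:
        proc = subprocess.run(
            [
                "Rscript", "--vanilla", "-e",
                "suppressMessages({library(lme4); library(jsonlite)})",
            ],
            capture_output=True, timeout=120,
        )
        return proc.returncode == 0
    except (OSError, subprocess.TimeoutExpired):
        return False


def fit_glmer(data, formula: str, timeout: float = 600.0) -> dict:
    """Fit a binomial cloglog `glmer` model and return its summary.

    Raises RuntimeError when R cannot be run or the model errors out.
    The returned dict carries ``terms/estimate/se/z/p`` vectors, the
    variance components, a ``singular`` flag and lme4 convergence
    ``messages`` (empty list = clean convergence).
    """
    with tempfile.TemporaryDirectory(prefix="phylonat_lme4_") as tmp:
        tmpdir = Path(tmp)
        data_path = tmpdir / "data.csv"
        formula_path = tmpdir / "formula.txt"
        script_path = tmpdir / "fit.R"
        out_path = tmpdir / "out.json"
        data.to_csv(data_path, index=False)
        formula_path.write_text(formula + "\n")
        script_path.write_text(_R_SCRIPT)
        try:
            proc = subprocess.run(
                [
                    "Rscript", "--vanilla", str(script_path),
                    str(data_path), str(formula_path), str(out_path),
                ],
                capture_output=True, timeout=timeout, text=True,
            )
        except (OSError, subprocess.TimeoutExpired) as exc:
            raise RuntimeError(f"could not run Rscript: {exc}") from exc
        if proc.returncode != 0 or not out_path.exists():
            raise RuntimeError(
                "glmer run failed: " + (proc.stderr or "")[-2000:]
            )
        res = json.loads(out_path.read_text())
    if not res.get("ok", False):
        raise RuntimeError(f"glmer error: {res.get('error')}")
    # jsonlite collapses length-1 vectors to scalars
    for key in ("terms", "estimate", "se", "z", "p",
                "vc_group", "vc_term", "vc_sd", "messages"):
        if key in res and not isinstance(res[key], list):
            res[key] = [res[key]]
        res.setdefault(key, [])
    return res
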