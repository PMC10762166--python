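"""Sandboxed execution of a submission's train and predict entrypoints.

Mirrors a container-based assessment workflow while keeping tests runnable
without a container daemon: a backend interface with two implementations,

* ``local_subprocess`` — runs the entrypoints as host subprocesses with the
  data/output directories passed through ``DATA_DIR``/``OUTPUT_DIR``
  environment variables (environment "build" is a no-op);
* ``container`` — builds the submission's Dockerfile and runs the
  entrypoints inside the image with ``/data`` mounted read-only and no
  network (requires a ``docker`` CLI on PATH).

The entrypoint contract: a submission directory provides ``train``/
``predict`` entrypoints (``train.py``/``predict.py`` or ``train.R``/
``predict.R``) that read ``$DATA_DIR/training.csv`` (and
``$DATA_DIR/testing.csv`` when present) and write
``$OUTPUT_DIR/train_predictions.csv`` (and ``test_predictions.csv``).

Isolation invariant: the mounted data directory contains the training
table with labels and, in final mode only, the testing table with every
label column stripped.  Testing labels are never staged, so no run can
read them.  In developmental mode the participant-facing view of an
outcome is the run status and nothing else.
"""

from __future__ import annotations

import os
import shutil
import subprocess
import sys
import tempfile
from dataclasses import dataclass, field
from pathlib import Path

from .cohort import LABEL_COLUMNS, CohortBundle
from .errors import ParameterError
from .submission import Submission

__all__ = [
    "RunRequest", "RunOutcome", "stage_data", "build_environment",
    "run_submission", "TRAINING_ONLY", "TRAINING_AND_TESTING",
]

TRAINING_ONLY = "training_only"
TRAINING_AND_TESTING = "training_and_testing"
BACKENDS = ("local_subprocess", "container")
DEFAULT_TIMEOUT = 1800.0   # seconds per entrypoint; configurable


@dataclass
class RunRequest:
    submission: Submission
    data_access: str = TRAINING_ONLY
    backend: str = "local_subprocess"
    timeout: float = DEFAULT_TIMEOUT
    repeat_index: int = 0
    admin_override: bool = False

    def __post_init__(self) -> None:
        if self.data_access not in (TRAINING_ONLY, TRAINING_AND_TESTING):
            raise ParameterError(f"bad data_access {self.data_access!r}")
        if self.backend not in BACKENDS:
            raise ParameterError(f"backend must be one of {BACKENDS}")
        # Developmental submissions never see the testing partition unless
        # the administrator explicitly overrides.
        if (self.submission.mode == "developmental"
                and not self.admin_override):
            self.data_access = TRAINING_ONLY


@dataclass
class RunOutcome:
    status: str                                  # "success" | "failure"
    predictions: dict[str, Path] = field(default_factory=dict)
    log: str = ""
    reason: str = ""

    @property
    def dev_visible(self) -> str:
        """All a participant sees of a developmental run."""
        return self.status


def stage_data(bundle: CohortBundle, data_dir: str | Path,
               include_testing: bool) -> Path:
    """Write the mounted data view: labels only ever for training."""
    data_dir = Path(data_dir)
    data_dir.mkdir(parents=True, exist_ok=True)
    if not bundle.partitions:
        raise ParameterError("bundle has no partitions; split the cohort first")
    train = bundle.subject_frame("training")
    train.to_csv(data_dir / "training.csv", index=False, lineterminator="\n")
    bundle.dictionary.to_frame().to_csv(data_dir / "data_dictionary.csv",
                                        index=False, lineterminator="\n")
    if include_testing:
        test = bundle.subject_frame("testing").drop(columns=LABEL_COLUMNS)
        test.to_csv(data_dir / "testing.csv", index=False, lineterminator="\n")
    for p in data_dir.iterdir():
        os.chmod(p, 0o444)
    return data_dir


def _entrypoint_command(code_root: Path, step: str) -> list[str] | None:
    py = code_root / f"{step}.py"
    if py.exists():
        return [sys.executable, str(py)]
    r = code_root / f"{step}.R"
    if r.exists():
        return ["Rscript", "--vanilla", str(r)]
    return None


def build_environment(submission: Submission,
                      backend: str = "local_subprocess") -> RunOutcome:
    """Build the execution environment; build failure is a first-class outcome.

    For ``local_subprocess`` the build is a no-op returning the host
    environment (reason carries the environment id).  For ``container`` the
    submission's recipe is built into an image tagged from the participant
    id and version tag; a failed build (e.g. a recipe naming a nonexistent
    package) returns a failure outcome whose log names the failing step.
    """
    if backend == "local_subprocess":
        return RunOutcome("success", reason="local", log="local host environment")
    recipe = submission.code_root / submission.environment_recipe
    if not recipe.exists():
        return RunOutcome("failure", reason="missing_recipe",
                          log=f"environment recipe {recipe} does not exist")
    if shutil.which("docker") is None:
        return RunOutcome("failure", reason="no_container_runtime",
                          log="docker CLI not found on PATH")
    tag = (f"harness-{submission.manifest.participant_id}"
           f"-{submission.manifest.version_tag}").lower().replace(" ", "-")
    proc = subprocess.run(
        ["docker", "build", "-t", tag, "-f", str(recipe),
         str(submission.code_root)],
        capture_output=True, text=True)
    if proc.returncode != 0:
        return RunOutcome("failure", reason="build_failed",
                          log=proc.stdout + proc.stderr)
    return RunOutcome("success", reason=tag, log=proc.stdout)


def _run_step_local(submission: Submission, step: str, data_dir: Path,
                    out_dir: Path, timeout: float) -> tuple[bool, str]:
    cmd = _entrypoint_command(submission.code_root, step)
    if cmd is None:
        return False, f"no {step} entrypoint (expected {step}.py or {step}.R)"
    env = dict(os.environ, DATA_DIR=str(data_dir), OUTPUT_DIR=str(out_dir))
    try:
        proc = subprocess.run(cmd, cwd=submission.code_root, env=env,
                              capture_output=True, text=True, timeout=timeout)
    except subprocess.TimeoutExpired:
        return False, f"{step} timed out after {timeout:.0f} s"
    log = proc.stdout + proc.stderr
    if proc.returncode != 0:
        return False, f"{step} exited with code {proc.returncode}\n{log}"
    return True, log


def _run_step_container(image: str, submission: Submission, step: str,
                        data_dir: Path, out_dir: Path,
                        timeout: float) -> tuple[bool, str]:
    suffix = ".py" if (submission.code_root / f"{step}.py").exists() else ".R"
    inner = (["python", f"/code/{step}.py"] if suffix == ".py"
             else ["Rscript", "--vanilla", f"/code/{step}.R"])
    cmd = ["docker", "run", "--rm", "--network", "none",
           "-v", f"{data_dir}:/data:ro", "-v", f"{out_dir}:/output",
           "-v", f"{submission.code_root}:/code:ro",
           "-e", "DATA_DIR=/data", "-e", "OUTPUT_DIR=/output",
           "-w", "/code", image] + inner
    try:
        proc = subprocess.run(cmd, capture_output=True, text=True, timeout=timeout)
    except subprocess.TimeoutExpired:
        return False, f"{step} timed out after {timeout:.0f} s"
    log = proc.stdout + proc.stderr
    if proc.returncode != 0:
        return False, f"{step} exited with code {proc.returncode}\n{log}"
    return True, log


def run_submission(request: RunRequest, bundle: CohortBundle,
                   workdir: str | Path | None = None) -> RunOutcome:
    """Execute train then predict; collect prediction files or a failure.

    On success the outcome carries ``train_predictions.csv`` and, when the
    request grants testing access, ``test_predictions.csv``.  A nonzero
    exit, a timeout, or a missing required prediction file yields a
    failure outcome with a reason code and the captured log.
    """
    cleanup = workdir is None
    workdir = Path(tempfile.mkdtemp(prefix="harness-run-")) if cleanup else Path(workdir)
    workdir.mkdir(parents=True, exist_ok=True)
    data_dir = workdir / "data"
    out_dir = workdir / "output"
    out_dir.mkdir(parents=True, exist_ok=True)
    include_testing = request.data_access == TRAINING_AND_TESTING
    stage_data(bundle, data_dir, include_testing)

    try:
        build = build_environment(request.submission, request.backend)
        if build.status != "success":
            return build
        logs = [build.log]
        for step in ("train", "predict"):
            if request.backend == "local_subprocess":
                ok, log = _run_step_local(request.submission, step, data_dir,
                                          out_dir, request.timeout)
            else:
                ok, log = _run_step_container(build.reason, request.submission,
                                              step, data_dir, out_dir,
                                              request.timeout)
            logs.append(log)
            if not ok:
                return RunOutcome("failure", log="\n".join(logs),
                                  reason=f"{step}_failed")

        required = {"training": out_dir / "train_predictions.csv"}
        if include_testing:
            required["testing"] = out_dir / "test_predictions.csv"
        missing = [p.name for p in required.values() if not p.exists()]
        if missing:
            return RunOutcome("failure", log="\n".join(logs),
                              reason=f"missing_output:{','.join(missing)}")
        if cleanup:
            # keep prediction files; move them out of the temp tree
            keep = Path(tempfile.mkdtemp(prefix="harness-preds-"))
            for part, p in required.items():
                target = keep / p.name
                shutil.copyfile(p, target)
                required[part] = target
        return RunOutcome("success", predictions=required, log="\n".join(logs))
    finally:
        if cleanup:
            shutil.rmtree(workdir, ignore_errors=True)
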