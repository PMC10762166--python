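"""The submission contract: manifest, integrity policy, and registry.

A submission is a directory containing a ``description.yaml`` manifest,
model code with ``train``/``predict`` entrypoints, and a container recipe.
The manifest must carry a participant id, a contact, a unique version tag,
and one model block per outcome (FSS and mortality) — missing tags were
the most common cause of failed submissions in practice, so the loader
names the offending field.

Integrity is enforced with sha256: a baseline digest is computed for every
protected file of the pristine template; a submission passes iff no
protected file was modified or removed.  Participants may freely add or
edit anything outside the protected set (their model code, their container
recipe).
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .errors import ManifestError, RegistrationError

__all__ = [
    "ModelInfo", "Manifest", "load_manifest", "IntegrityPolicy",
    "IntegrityReport", "verify_integrity", "Submission",
    "SubmissionRegistry", "sha256_file", "DEFAULT_PROTECTED_PATHS",
]

OUTCOMES = ("FSS", "mortality")

#: Files of the participant template that must not be edited: the i/o
#: contract stubs that load the mounted data and write prediction files.
#: The set is configurable per challenge.
DEFAULT_PROTECTED_PATHS = ("io_contract.py",)


@dataclass(frozen=True)
class ModelInfo:
    outcome: str            # "FSS" | "mortality"
    approach: str           # e.g. "Random Forest"
    language: str           # e.g. "R", "python"
    predictors: int         # declared predictor count (parsimony proxy)
    summary: str = ""


@dataclass(frozen=True)
class Manifest:
    participant_id: str
    contact: str
    version_tag: str
    models: tuple[ModelInfo, ...]

    def model_for(self, outcome: str) -> ModelInfo:
        for m in self.models:
            if m.outcome == outcome:
                return m
        raise ManifestError(f"manifest has no model block for outcome {outcome}")


def load_manifest(path: str | Path) -> Manifest:
    """Parse and check a description.yaml manifest.

    Errors name the missing or malformed field so the administrator can
    return actionable feedback.
    """
    path = Path(path)
    if not path.exists():
        raise ManifestError(f"manifest file {path} does not exist")
    try:
        raw = yaml.safe_load(path.read_text())
    except yaml.YAMLError as exc:
        raise ManifestError(f"cannot parse {path}: {exc}") from exc
    if not isinstance(raw, dict):
        raise ManifestError(f"{path.name}: manifest must be a mapping")

    for fieldname in ("participant_id", "contact", "version_tag"):
        value = raw.get(fieldname)
        if value is None or str(value).strip() == "":
            raise ManifestError(f"{path.name}: missing required field {fieldname}")

    blocks = raw.get("models")
    if not isinstance(blocks, list) or not blocks:
        raise ManifestError(f"{path.name}: missing required field models")
    models = []
    seen = set()
    for i, block in enumerate(blocks):
        if not isinstance(block, dict):
            raise ManifestError(f"{path.name}: models[{i}] must be a mapping")
        outcome = block.get("outcome")
        if outcome not in OUTCOMES:
            raise ManifestError(
                f"{path.name}: models[{i}].outcome must be one of {OUTCOMES}, "
                f"got {outcome!r}")
        if outcome in seen:
            raise ManifestError(
                f"{path.name}: duplicate model block for outcome {outcome}")
        seen.add(outcome)
        for key in ("approach", "language"):
            if not str(block.get(key, "")).strip():
                raise ManifestError(
                    f"{path.name}: models[{i}] ({outcome}) missing field {key}")
        predictors = block.get("predictors", 0)
        if not isinstance(predictors, int) or predictors < 0:
            raise ManifestError(
                f"{path.name}: models[{i}].predictors must be a nonnegative "
                f"integer, got {predictors!r}")
        models.append(ModelInfo(outcome, str(block["approach"]),
                                str(block["language"]), predictors,
                                str(block.get("summary", ""))))
    missing_outcomes = [o for o in OUTCOMES if o not in seen]
    if missing_outcomes:
        raise ManifestError(
            f"{path.name}: missing model block(s) for outcome(s): "
            f"{', '.join(missing_outcomes)}")
    return Manifest(str(raw["participant_id"]), str(raw["contact"]),
                    str(raw["version_tag"]), tuple(models))


def sha256_file(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


@dataclass(frozen=True)
class IntegrityPolicy:
    """Protected paths with their pristine-template sha256 digests."""

    protected_paths: tuple[str, ...]
    baseline_digests: dict[str, str]

    def __post_init__(self) -> None:
        missing = set(self.protected_paths) - set(self.baseline_digests)
        if missing:
            raise ManifestError(
                f"integrity policy lacks baseline digests for: {sorted(missing)}")

    @classmethod
    def from_template(cls, template_root: str | Path,
                      protected_paths: tuple[str, ...] = DEFAULT_PROTECTED_PATHS,
                      ) -> "IntegrityPolicy":
        root = Path(template_root)
        digests = {}
        for rel in protected_paths:
            p = root / rel
            if not p.exists():
                raise ManifestError(f"protected file {rel} missing from template {root}")
            digests[rel] = sha256_file(p)
        return cls(tuple(protected_paths), digests)

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(
            {"protected_paths": list(self.protected_paths),
             "baseline_digests": self.baseline_digests}, indent=1) + "\n")

    @classmethod
    def from_json(cls, path: str | Path) -> "IntegrityPolicy":
        raw = json.loads(Path(path).read_text())
        return cls(tuple(raw["protected_paths"]), dict(raw["baseline_digests"]))


@dataclass
class IntegrityReport:
    statuses: dict[str, str]    # path -> unchanged | modified | missing

    @property
    def passed(self) -> bool:
        return all(s == "unchanged" for s in self.statuses.values())

    def violations(self) -> dict[str, str]:
        return {p: s for p, s in self.statuses.items() if s != "unchanged"}


@dataclass
class Submission:
    """A participant deliverable: manifest + code directory + mode."""

    manifest: Manifest
    code_root: Path
    mode: str = "developmental"          # "developmental" | "final"
    environment_recipe: str = "Dockerfile"

    def __post_init__(self) -> None:
        if self.mode not in ("developmental", "final"):
            raise RegistrationError(f"mode must be developmental/final, got {self.mode!r}")
        # absolute: the path doubles as the subprocess working directory
        self.code_root = Path(self.code_root).resolve()

    @classmethod
    def from_directory(cls, path: str | Path, mode: str = "developmental") -> "Submission":
        root = Path(path)
        manifest = load_manifest(root / "description.yaml")
        return cls(manifest, root, mode)


def verify_integrity(submission: Submission,
                     policy: IntegrityPolicy) -> IntegrityReport:
    """Report each protected path as unchanged, modified, or missing.

    A pure function of file bytes: copying a submission directory yields an
    identical report.  Files added outside the protected set never fail the
    check.
    """
    statuses = {}
    for rel in policy.protected_paths:
        p = submission.code_root / rel
        if not p.exists():
            statuses[rel] = "missing"
            continue
        try:
            digest = sha256_file(p)
        except OSError as exc:
            raise OSError(f"cannot read protected file {p}: {exc}") from exc
        statuses[rel] = "unchanged" if digest == policy.baseline_digests[rel] else "modified"
    return IntegrityReport(statuses)


class SubmissionRegistry:
    """Tracks submissions per participant; at most one final each.

    Developmental submissions are unlimited (participants use them to
    verify their code runs to completion); a duplicate
    (participant, version_tag) or a second final submission is rejected.
    """

    def __init__(self) -> None:
        self._entries: list[Submission] = []

    def register(self, submission: Submission) -> None:
        pid = submission.manifest.participant_id
        tag = submission.manifest.version_tag
        for prior in self._entries:
            pm = prior.manifest
            if pm.participant_id == pid and pm.version_tag == tag:
                raise RegistrationError(
                    f"duplicate submission tag {tag!r} for participant {pid}")
            if (pm.participant_id == pid and prior.mode == "final"
                    and submission.mode == "final"):
                raise RegistrationError(
                    f"participant {pid} already has a final submission "
                    f"(tag {pm.version_tag!r}); only one final submission is allowed")
        self._entries.append(submission)

    def submissions(self, participant_id: str | None = None,
                    mode: str | None = None) -> list[Submission]:
        out = self._entries
        if participant_id is not None:
            out = [s for s in out if s.manifest.participant_id == participant_id]
        if mode is not None:
            out = [s for s in out if s.mode == mode]
        return list(out)

    def final_submission(self, participant_id: str) -> Submission | None:
        finals = self.submissions(participant_id, mode="final")
        return finals[0] if finals else None

    @property
    def participants(self) -> list[str]:
        return sorted({s.manifest.participant_id for s in self._entries})
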