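"""Verify a submission's protected files with sha256 integrity checks.

Writes the pristine template, tampers with the protected i/o stub, and
shows how the report distinguishes allowed edits from forbidden ones.
"""

import shutil
import tempfile
from pathlib import Path

import challenge_harness as ch
from challenge_harness.submission import Submission

workdir = Path(tempfile.mkdtemp(prefix="example-"))
pristine = ch.write_python_template(workdir / "pristine")
policy = ch.template_policy(pristine)

edited = workdir / "edited"
shutil.copytree(pristine, edited)
(edited / "my_model.py").write_text("N_TREES = 500\n")          # allowed
stub = edited / "io_contract.py"
stub.write_text(stub.read_text() + "\n# sneaky edit\n")         # forbidden

for name, root in (("pristine", pristine), ("edited", edited)):
    report = ch.verify_integrity(Submission.from_directory(root), policy)
    verdict = "PASS" if report.passed else f"FAIL {report.violations()}"
    print(f"{name}: {verdict}")
# Adding model files never fails the check; any byte changed in a
# protected stub flips its sha256 and is reported as modified.
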