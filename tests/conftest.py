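import datetime

import pytest

from colorecall.extraction import ExtractionConfig
from colorecall.synth import ScenarioConfig, generate_corpus


@pytest.fixture(scope="session")
def config():
    return ExtractionConfig()


@pytest.fixture(scope="session")
def small_corpus():
    """A 300-report noise-free corpus shared by closed-loop tests."""
    return generate_corpus(ScenarioConfig(n_reports=300, seed=11))


def truth_record(t):
    """Ground-truth row in the shape classify_outcome expects."""
    return {
        "true_due_date": t.due_date.isoformat() if t.due_date else "",
        "true_label": t.label if t.label != "no_date" else "",
    }


@pytest.fixture
def write_manifest_corpus(tmp_path):
    """Write a tiny hand-built manifest + report files; returns paths."""

    def _write(rows):
        reports_dir = tmp_path / "reports"
        reports_dir.mkdir(exist_ok=True)
        lines = ["report_id,patient_id,file,scan_date,linked_procedure_date"]
        for r in rows:
            if r.get("text") is not None:
                (reports_dir / r["file"]).write_text(r["text"], encoding="utf-8")
            lines.append(
                f"{r['report_id']},{r['patient_id']},{r['file']},"
                f"{r.get('scan_date', '2023-02-01')},{r.get('linked', '')}"
            )
        manifest = tmp_path / "manifest.csv"
        manifest.write_text("\n".join(lines) + "\n", encoding="utf-8")
        return manifest, reports_dir

    return _write
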