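from datetime import datetime

import pytest

from pathmarker.model import RawReport
from pathmarker.pipeline import Normalizers
from pathmarker.synthesis import Vocabulary


@pytest.fixture(scope="session")
def vocab() -> Vocabulary:
    return Vocabulary.bundled()


@pytest.fixture(scope="session")
def normalizers(vocab) -> Normalizers:
    return Normalizers.from_vocabulary(vocab)


def make_report(text: str, report_type: str = "IHC", report_id: str = "R1",
                patient_id: str = "P1", timestamp=datetime(2012, 3, 1)) -> RawReport:
    return RawReport(
        report_id=report_id,
        patient_id=patient_id,
        report_type=report_type,
        timestamp=timestamp,
        text=text,
    )
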