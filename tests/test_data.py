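import math

import numpy as np
import pytest
from hypothesis import given, strategies as st

from neckteeth.data import (
    InductionWeights,
    JuvenileRecord,
    LandmarkSet,
    RecordValidationError,
    SchemaError,
    landmark_lengths,
    make_mother_uid,
    read_juvenile_table,
    tollrian_induction_score,
    write_juvenile_table,
)

DEFAULT_W = InductionWeights()


class TestMotherUid:
    def test_format_and_determinism(self):
        assert make_mother_uid("UNI", True, False, 3) == "UNI.K1.U0.3"
        assert make_mother_uid("P5", False, False, 1) == "P5.K0.U0.1"
        assert make_mother_uid("UNI", True, False, 3) == make_mother_uid("UNI", True, False, 3)

    def test_injective_over_cells_and_indices(self):
        uids = {
            make_mother_uid(c, k, u, i)
            for c in ("UNI", "P5")
            for k in (False, True)
            for u in (False, True)
            for i in (1, 2, 3, 4)
        }
        assert len(uids) == 2 * 2 * 2 * 4

    def test_invalid_index(self):
        with pytest.raises(ValueError):
            make_mother_uid("UNI", True, False, 0)


class TestInductionScore:
    @pytest.mark.parametrize(
        "teeth,pedestal,expected",
        [(0, "A", 0.0), (3, "B", 60.0), (5, "C", 100.0), (2, "A", 20.0), (0, "C", 50.0)],
    )
    def test_default_weights(self, teeth, pedestal, expected):
        assert tollrian_induction_score(teeth, pedestal, DEFAULT_W) == expected

    def test_cap_applies(self):
        # 50 + 5*10 = 100 exactly hits the cap with defaults
        w = InductionWeights(per_tooth_percent=15, cap=100)
        assert tollrian_induction_score(5, "C", w) == 100.0

    def test_negative_weights_rejected(self):
        with pytest.raises(ValueError):
            InductionWeights(per_tooth_percent=-1)

    @given(
        teeth=st.integers(0, 5),
        pedestal=st.sampled_from(["A", "B", "C"]),
    )
    def test_monotone_in_teeth_and_pedestal(self, teeth, pedestal):
        score = tollrian_induction_score(teeth, pedestal, DEFAULT_W)
        if teeth < 5:
            assert tollrian_induction_score(teeth + 1, pedestal, DEFAULT_W) >= score
        nxt = {"A": "B", "B": "C"}.get(pedestal)
        if nxt:
            assert tollrian_induction_score(teeth, nxt, DEFAULT_W) >= score
        assert 0.0 <= score <= 100.0


class TestLandmarks:
    def test_axis_aligned_body_length(self):
        lm = LandmarkSet(
            head_top=(0.10, 0.90),
            spina_base=(0.10, 0.20),
            spina_tip=(0.10, 0.10),
            ventral_mid=(0.0, 0.5),
            dorsal_mid=(0.2, 0.5),
        )
        bl, bw, sl = landmark_lengths(lm)
        assert bl == pytest.approx(0.70)
        assert bw == pytest.approx(0.20)
        assert sl == pytest.approx(0.10)

    def test_pythagorean_width_and_degenerate_spina(self):
        lm = LandmarkSet(
            head_top=(0, 1),
            spina_base=(0.5, 0.5),
            spina_tip=(0.5, 0.5),
            ventral_mid=(0, 0),
            dorsal_mid=(0.3, 0.4),
        )
        _, bw, sl = landmark_lengths(lm)
        assert bw == pytest.approx(0.5)
        assert sl == 0.0

    def test_missing_landmark_identified(self):
        with pytest.raises(ValueError, match="spina_tip"):
            LandmarkSet(
                head_top=(0, 1),
                spina_base=(0, 0),
                spina_tip=None,
                ventral_mid=(0, 0),
                dorsal_mid=(1, 0),
            )

    @given(
        angle=st.floats(0, 2 * math.pi, allow_nan=False),
        dx=st.floats(-5, 5),
        dy=st.floats(-5, 5),
    )
    def test_rigid_motion_invariance(self, angle, dx, dy):
        pts = {
            "head_top": (0.1, 0.9),
            "spina_base": (0.15, 0.2),
            "spina_tip": (0.18, 0.05),
            "ventral_mid": (0.0, 0.5),
            "dorsal_mid": (0.3, 0.55),
        }
        base = landmark_lengths(LandmarkSet(**pts))
        c, s = math.cos(angle), math.sin(angle)
        moved = {
            k: (c * x - s * y + dx, s * x + c * y + dy) for k, (x, y) in pts.items()
        }
        rotated = landmark_lengths(LandmarkSet(**moved))
        assert rotated == pytest.approx(base, abs=1e-9)


class TestRecordInvariants:
    def test_instar2_requires_survival(self):
        with pytest.raises(RecordValidationError):
            JuvenileRecord(
                clone="UNI", kairomone=False, uvr=False, instar=2, mother_uid="m",
                neckteeth=0, pedestal="A", survived_to_instar2=False,
            )

    @pytest.mark.parametrize("teeth", [-1, 6])
    def test_neckteeth_bounds(self, teeth):
        with pytest.raises(RecordValidationError):
            JuvenileRecord(
                clone="UNI", kairomone=False, uvr=False, instar=1, mother_uid="m",
                neckteeth=teeth, pedestal="A",
            )

    def test_nonpositive_length_rejected(self):
        with pytest.raises(RecordValidationError):
            JuvenileRecord(
                clone="UNI", kairomone=False, uvr=False, instar=1, mother_uid="m",
                neckteeth=0, pedestal="A", body_length=0.0,
            )


class TestTableIO:
    def _records(self):
        recs = []
        for i in range(10):
            recs.append(
                JuvenileRecord(
                    clone="UNI" if i % 2 else "P5",
                    kairomone=bool(i % 2),
                    uvr=False,
                    instar=1,
                    mother_uid=make_mother_uid("UNI" if i % 2 else "P5", bool(i % 2), False, 1 + i // 2),
                    neckteeth=i % 6,
                    pedestal="ABC"[i % 3],
                    body_length=round(0.6 + 0.01 * i, 6),
                    body_width=None if i == 4 else round(0.35 + 0.005 * i, 6),
                    spina_length=round(0.4 + 0.002 * i, 6),
                    survived_to_instar2=True,
                )
            )
        return recs

    def test_round_trip_identity(self, tmp_path):
        recs = self._records()
        path = tmp_path / "juveniles.csv"
        write_juvenile_table(recs, path)
        back = read_juvenile_table(path)
        assert back == recs

    def test_missing_lengths_stay_missing(self, tmp_path):
        recs = self._records()
        path = tmp_path / "juveniles.csv"
        write_juvenile_table(recs, path)
        back = read_juvenile_table(path)
        assert back[4].body_width is None

    def test_invalid_pedestal_names_row(self, tmp_path):
        recs = self._records()
        path = tmp_path / "juveniles.csv"
        write_juvenile_table(recs, path)
        text = path.read_text().splitlines()
        text[4] = text[4].replace(",A,", ",D,")
        path.write_text("\n".join(text))
        with pytest.raises(RecordValidationError, match="row 3"):
            read_juvenile_table(path)

    def test_landmark_table_round_trip(self, tmp_path):
        from neckteeth.data import read_landmark_table, write_landmark_table

        sets = [
            LandmarkSet(
                head_top=(0.1, 0.9), spina_base=(0.15, 0.2), spina_tip=(0.18, 0.05),
                ventral_mid=(0.0, 0.5), dorsal_mid=(0.3, 0.55),
            ),
            LandmarkSet(
                head_top=(0.2, 1.0), spina_base=(0.25, 0.3), spina_tip=(0.28, 0.15),
                ventral_mid=(0.1, 0.6), dorsal_mid=(0.4, 0.65),
            ),
        ]
        path = tmp_path / "landmarks.csv"
        write_landmark_table(sets, path)
        back = read_landmark_table(path)
        assert back == sets
        bl, bw, sl = landmark_lengths(back[0])
        assert bl == pytest.approx(landmark_lengths(sets[0])[0])

    def test_missing_column_is_schema_error(self, tmp_path):
        recs = self._records()
        path = tmp_path / "juveniles.csv"
        write_juvenile_table(recs, path)
        import pandas as pd

        frame = pd.read_csv(path).drop(columns=["neckteeth"])
        frame.to_csv(path, index=False)
        with pytest.raises(SchemaError, match="neckteeth"):
            read_juvenile_table(path)
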