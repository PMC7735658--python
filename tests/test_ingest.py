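import json
import textwrap
from datetime import date, datetime

import pytest
from hypothesis import given
from hypothesis import strategies as st

from forumlisten.ingest import (
    EXCLUDED,
    FILTER_RULES,
    RawPost,
    UserProfile,
    build_cohort,
    days_postop,
    map_treatment_group,
    read_posts,
    read_profiles,
)


class TestReadPosts:
    def test_valid_rows_pass_through(self, posts_csv):
        posts = read_posts(posts_csv)
        assert len(posts) == 3
        assert posts[0].user_id == "u1"
        assert posts[0].posted_at == datetime(2015, 1, 11, 9, 0)
        assert all(p.is_thread_initial for p in posts)

    def test_malformed_row_logged_not_dropped_silently(self, tmp_path, caplog):
        path = tmp_path / "posts.csv"
        path.write_text(
            "user_id,thread_id,is_thread_initial,subject,posted_at\n"
            "u1,t1,true,ok,2015-01-02T00:00:00\n"
            "u2,t2,true,missing timestamp,\n"
            "u3,t3,true,ok too,2015-01-03T00:00:00\n"
        )
        with caplog.at_level("WARNING"):
            posts = read_posts(path)
        assert len(posts) == 2
        assert any("rejected" in rec.message for rec in caplog.records)

    def test_header_only_file_is_empty_not_error(self, tmp_path):
        path = tmp_path / "posts.csv"
        path.write_text("user_id,thread_id,is_thread_initial,subject,posted_at\n")
        assert read_posts(path) == []

    def test_missing_column_is_fatal_and_names_it(self, tmp_path):
        path = tmp_path / "posts.csv"
        path.write_text("user_id,thread_id,subject,posted_at\nu,t,s,2015-01-01T00:00:00\n")
        with pytest.raises(ValueError, match="is_thread_initial"):
            read_posts(path)

    def test_missing_file_is_fatal(self, tmp_path):
        with pytest.raises(FileNotFoundError):
            read_posts(tmp_path / "nope.csv")

    def test_jsonl_roundtrip(self, tmp_path):
        path = tmp_path / "posts.jsonl"
        recs = [
            {"user_id": "u1", "thread_id": "t1", "is_thread_initial": True,
             "subject": "hi", "posted_at": "2015-01-05T08:00:00"},
            {"user_id": "u2", "thread_id": "t2", "is_thread_initial": False,
             "subject": "", "posted_at": "2015-01-06T08:00:00"},
        ]
        path.write_text("\n".join(json.dumps(r) for r in recs) + "\n")
        posts = read_posts(path, format="jsonl")
        assert len(posts) == 2
        assert posts[1].subject == ""
        assert posts[1].is_thread_initial is False


class TestReadProfiles:
    def test_read(self, profiles_csv):
        profiles = read_profiles(profiles_csv)
        assert profiles["u1"].hysterectomy_type == "TLH"
        assert profiles["u1"].surgery_date == date(2015, 1, 1)
        assert profiles["u2"].ovary_status == "both_removed"

    def test_duplicate_keeps_first_with_warning(self, tmp_path, caplog):
        path = tmp_path / "profiles.csv"
        path.write_text(
            "user_id,hysterectomy_type,surgery_date,ovary_status\n"
            "u1,TAH,2015-01-01,unknown\n"
            "u1,TVH,2015-02-01,unknown\n"
        )
        with caplog.at_level("WARNING"):
            profiles = read_profiles(path)
        assert profiles["u1"].hysterectomy_type == "TAH"
        assert any("duplicate" in rec.message for rec in caplog.records)

    def test_blank_fields_become_none(self, tmp_path):
        path = tmp_path / "profiles.csv"
        path.write_text(
            "user_id,hysterectomy_type,surgery_date,ovary_status\nu1,,,\n"
        )
        prof = read_profiles(path)["u1"]
        assert prof.hysterectomy_type is None
        assert prof.surgery_date is None
        assert prof.ovary_status == "unknown"


class TestMapTreatmentGroup:
    @pytest.mark.parametrize(
        "code,group",
        [
            ("TAH", "abdominal"),
            ("SAH", "abdominal"),
            ("TAH/SAH", "abdominal"),
            ("TVH", "vaginal"),
            ("LAVH", "vaginal"),
            ("TLH", "laparoscopic"),
            ("LSH", "laparoscopic"),
            ("DVH", "laparoscopic"),
        ],
    )
    def test_box1_mapping(self, code, group):
        assert map_treatment_group(code) == group

    @pytest.mark.parametrize("code", ["SILS", "LESS", "sils"])
    def test_single_incision_excluded(self, code):
        assert map_treatment_group(code) == EXCLUDED

    def test_unknown_code_excluded_with_warning(self, caplog):
        with caplog.at_level("WARNING"):
            assert map_treatment_group("XYZ") == EXCLUDED
        assert any("unknown" in rec.message for rec in caplog.records)


class TestDaysPostop:
    def test_same_day_is_zero(self):
        assert days_postop(datetime(2015, 1, 1, 23, 59), date(2015, 1, 1)) == 0

    def test_boundary_84(self):
        assert days_postop(date(2015, 3, 26), date(2015, 1, 1)) == 84

    def test_negative_before_surgery(self):
        assert days_postop(date(2014, 12, 31), date(2015, 1, 1)) == -1


def _post(user="u1", day_offset=10, initial=True, tid="t1"):
    return RawPost(
        user_id=user,
        thread_id=tid,
        is_thread_initial=initial,
        subject="some subject",
        posted_at=datetime(2015, 1, 1 + day_offset, 12, 0),
    )


def _profile(user="u1", htype="TLH", sdate=date(2015, 1, 1), ovary="unknown"):
    return UserProfile(user_id=user, hysterectomy_type=htype, surgery_date=sdate, ovary_status=ovary)


class TestBuildCohort:
    def test_all_filters_pass(self):
        cohort, log = build_cohort([_post()], {"u1": _profile()})
        assert len(cohort) == 1
        assert cohort[0].treatment_group == "laparoscopic"
        assert cohort[0].days_postop == 10
        assert cohort[0].week_postop == 2
        assert log.total_out == 1

    def test_window_rule_excludes_day_90(self):
        # Jan 1 surgery; post on Apr 1 is day 90
        post = RawPost("u1", "t1", True, "late", datetime(2015, 4, 1))
        cohort, log = build_cohort([post], {"u1": _profile()})
        assert cohort == []
        assert log.removed["outside_window"] == 1

    def test_day_84_retained_day_85_excluded(self):
        posts = [
            RawPost("u1", "t1", True, "on the edge", datetime(2015, 3, 26)),
            RawPost("u1", "t2", True, "just past", datetime(2015, 3, 27)),
        ]
        cohort, log = build_cohort(posts, {"u1": _profile()})
        assert [c.days_postop for c in cohort] == [84]
        assert cohort[0].week_postop == 13
        assert log.removed["outside_window"] == 1

    def test_reply_posts_excluded(self):
        cohort, log = build_cohort([_post(initial=False)], {"u1": _profile()})
        assert cohort == []
        assert log.removed["not_thread_initial"] == 1

    def test_undeclared_type_or_date_excluded(self):
        cohort, log = build_cohort(
            [_post(), _post(user="u2", tid="t2")],
            {"u1": _profile(htype=None), "u2": _profile(user="u2", sdate=None)},
        )
        assert cohort == []
        assert log.removed["undeclared_profile"] == 2

    def test_missing_profile_excluded(self):
        cohort, log = build_cohort([_post(user="nobody")], {})
        assert cohort == []
        assert log.removed["undeclared_profile"] == 1

    def test_sils_user_excluded(self):
        cohort, log = build_cohort([_post()], {"u1": _profile(htype="SILS")})
        assert cohort == []
        assert log.removed["excluded_type"] == 1

    def test_ovary_status_never_filters(self):
        for ovary in ("kept_at_least_one", "both_removed", "unknown"):
            cohort, _ = build_cohort([_post()], {"u1": _profile(ovary=ovary)})
            assert len(cohort) == 1
            assert cohort[0].ovary_status == ovary

    def test_empty_output_is_legal(self, caplog):
        with caplog.at_level("WARNING"):
            cohort, _ = build_cohort([], {})
        assert cohort == []

    @given(
        st.lists(
            st.tuples(
                st.sampled_from(["u1", "u2", "u3", "ghost"]),
                st.integers(min_value=-10, max_value=100),
                st.booleans(),
            ),
            max_size=40,
        )
    )
    def test_attrition_accounting_conserves_posts(self, rows):
        posts = [
            RawPost(u, f"t{i}", init, "s", datetime(2015, 1, 1) + __import__("datetime").timedelta(days=max(d, -360) + 360))
            for i, (u, d, init) in enumerate(rows)
        ]
        profiles = {
            "u1": _profile(user="u1", sdate=date(2015, 12, 27)),
            "u2": _profile(user="u2", htype="SILS", sdate=date(2015, 12, 27)),
            "u3": _profile(user="u3", htype=None, sdate=date(2015, 12, 27)),
        }
        cohort, log = build_cohort(posts, profiles)
        assert len(cohort) <= len(posts)
        assert sum(log.removed.values()) == len(posts) - len(cohort)
        assert set(log.removed) == set(FILTER_RULES)
        assert all(0 <= c.days_postop <= 84 for c in cohort)

    def test_deterministic_rerun(self, posts_csv, profiles_csv):
        out1 = build_cohort(read_posts(posts_csv), read_profiles(profiles_csv))
        out2 = build_cohort(read_posts(posts_csv), read_profiles(profiles_csv))
        assert out1[0] == out2[0]
        assert out1[1].as_dict() == out2[1].as_dict()


def test_week_postop_convention():
    from tests.conftest import make_post

    assert make_post(day=0).week_postop == 1
    assert make_post(day=6).week_postop == 1
    assert make_post(day=7).week_postop == 2
    assert make_post(day=83).week_postop == 12
    assert make_post(day=84).week_postop == 13
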