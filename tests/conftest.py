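import textwrap

import pytest

from forumlisten.ingest import CohortPost
from forumlisten.taxonomy import TaggedPost, default_taxonomy


@pytest.fixture(scope="session")
def taxonomy():
    return default_taxonomy()


def make_post(user="u1", group="abdominal", subject="hello", day=5, ovary="unknown"):
    return CohortPost(
        user_id=user, treatment_group=group, ovary_status=ovary, subject=subject, days_postop=day
    )


def make_tagged(user="u1", group="abdominal", day=5, mentions=(), subject="x"):
    return TaggedPost(
        post=make_post(user=user, group=group, subject=subject, day=day),
        mentioned_groups=frozenset(mentions),
    )


@pytest.fixture
def posts_csv(tmp_path):
    path = tmp_path / "posts.csv"
    path.write_text(
        textwrap.dedent(
            """\
            user_id,thread_id,is_thread_initial,subject,posted_at
            u1,t1,true,Terrible pain and spotting,2015-01-11T09:00:00
            u1,t2,true,Week two update,2015-01-15T10:30:00
            u2,t3,true,Swelly belly question,2015-02-05T12:00:00
            """
        )
    )
    return path


@pytest.fixture
def profiles_csv(tmp_path):
    path = tmp_path / "profiles.csv"
    path.write_text(
        textwrap.dedent(
            """\
            user_id,hysterectomy_type,surgery_date,ovary_status
            u1,TLH,2015-01-01,kept_at_least_one
            u2,TAH,2015-02-01,both_removed
            """
        )
    )
    return path
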