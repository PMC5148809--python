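import itertools
from datetime import timedelta

import pytest

from concernsurv import StudyWindow, TweetRecord


@pytest.fixture
def window():
    return StudyWindow()


@pytest.fixture
def make_tweet(window):
    """Factory for in-window tweets at a fractional-day offset from origin."""
    counter = itertools.count()

    def _make(
        user="u1",
        day=0.0,
        text="こんにちは",
        retweet=False,
        tweet_id=None,
        username=None,
    ):
        i = next(counter)
        return TweetRecord(
            tweet_id=tweet_id or f"t{i:06d}",
            user_id=user,
            username=username,
            timestamp=window.start + timedelta(days=day),
            text=text,
            is_retweet=retweet,
        )

    return _make
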