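"""Synthetic forum-corpus generator with planted gold labels.

Emulates the structure of a scraped online health community so the whole
pipeline is testable without any download:

* three author populations with distinct writing signatures — patients
  (first-person symptom talk), caregivers (kinship-referential talk) and
  specialists (second-person advice talk);
* five topic vocabularies keyed to UMLS-style semantic-type term pools
  (symptom/sosy, complication/dsyn+patf, examination/diap+lbpr,
  procedure/topp, drug/phsu) per disease forum;
* heavily skewed posting volume (specialists post an order of magnitude
  more than patients or caregivers);
* a controllable mixture of informational and emotional messages, with
  per-group polarity mix, emotional intensity and an optional linear
  trend in polarity over each author's first year.

Text is template-based slot filling: every lexical signal is planted
deliberately, and gold labels for member group, message topic,
informational/emotional status and polarity are emitted alongside the
corpus in a separate structure the pipeline can never read implicitly.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from datetime import datetime, timedelta
from pathlib import Path
from typing import Literal

import numpy as np
from pydantic import BaseModel, Field, model_validator

from .corpus_io import Corpus, Message

Group = Literal["patient", "caregiver", "specialist", "member"]

TOPICS = ("symptom", "complication", "examination", "procedure", "drug")

# Five semantic-type term pools per disease forum.
TOPIC_POOLS: dict[str, dict[str, list[str]]] = {
    "lung_cancer": {
        "symptom": [
            "cough", "pain", "breathless", "symptoms", "chest pain", "painful",
            "shortness of breath", "wheezing", "short of breath",
            "coughing up blood", "nausea",
        ],
        "complication": [
            "infection", "bronchitis", "pneumonia", "tuberculosis", "asthma",
            "pleural effusion", "copd", "emphysema", "collapsed lung", "atelectasis",
        ],
        "examination": [
            "scans", "x-ray", "cat scan", "mri", "biopsy", "pet scan",
            "chest x-ray", "imaging", "biopsy needle", "bronchoscopy",
        ],
        "procedure": [
            "chemo", "operation", "surgery", "radiation", "therapy",
            "chemotherapy", "removal", "radiation therapy", "wedge resection",
            "lobectomy",
        ],
        "drug": [
            "silicas", "morphine", "advil", "tarceva", "chantix", "carboplatin",
            "alimta", "dilaudid", "taxol", "coumadin",
        ],
    },
    "diabetes": {
        "drug": [
            "insulin", "lantus", "januvia", "metformin", "glucophage", "actos",
            "avandia", "amaryl", "marijuana", "glipizide",
        ],
        "complication": [
            "infection", "hypoglycemia", "low blood sugar", "dka", "obesity",
            "pcos", "kidney disease", "coma", "diabetic neuropathy", "bgs",
        ],
        "symptom": [
            "pain", "tired", "thirsty", "nausea", "fatigue", "frequent urination",
            "hungry", "dizzy", "itchy", "sore", "tingling",
        ],
        "examination": [
            "blood test", "glucose test", "fasting test", "fasting blood sugar",
            "cat scan", "hemoglobin a1c test", "gtts", "glucose tolerance test",
            "mri",
        ],
        "procedure": [
            "infusion", "therapy", "injection", "transplant", "dialysis", "rx",
            "ect", "insulin injection", "cde", "amputation",
        ],
    },
    "breast_cancer": {
        "examination": [
            "biopsy", "mri", "ultrasound", "mammogram", "screening", "bi-rads",
            "core biopsy", "cat scan", "imaging", "biopsy needle",
        ],
        "procedure": [
            "chemo", "operation", "chemotherapy", "radiation", "radiotherapy",
            "mastectomy", "lumpectomy", "implant", "removal", "surgical",
        ],
        "symptom": [
            "sore", "pain", "painful", "breast pain", "nipple discharge",
            "itching", "tingling", "hot flashes", "nausea", "itchy",
        ],
        "drug": [
            "tamoxifen", "arimidex", "taxol", "femara", "taxotere", "carboplatin",
            "effexor", "docetaxel", "valium", "raloxifene",
        ],
        "complication": [
            "infection", "rash", "lymph edema", "fibrocystic breast", "mastitis",
            "idc", "eczema", "complex cyst", "complex cysts", "neuropathy",
        ],
    },
}

KINSHIP_TERMS = [
    "husband", "wife", "mother", "father", "mom", "dad", "sister", "brother",
    "son", "daughter", "aunt", "uncle", "grandmother", "grandfather",
    "father in law", "mother in law",
]

# Informational sentence pools. Every message draws an opener, a middle
# and a closer independently, so a group's signature is the *support* of
# its pool — no single template can become a spurious sub-cluster.
# Sentiment-lexicon words inside them are kept weak (any opener + middle
# + closer combination totals <= 0.875 subjectivity, below tau = 1.0).
# Within each group and slot the sentences are micro-variants of one
# skeleton: the shared word sequence is the group's dense lexical
# signature (present in every message), while the variation is confined
# to a few single-word alternations. This keeps within-group n-gram
# variance low and spread out, so no sentence can act as a sub-cluster.
SENTENCE_POOLS: dict[str, dict[str, list[str]]] = {
    "patient": {
        "opener": [
            "i have been having {t1} for two weeks now.",
            "i have been having {t1} for two months now.",
            "i have been noticing {t1} for two weeks now.",
            "i have been having {t1} since last month.",
            "i have been noticing {t1} since last month.",
        ],
        "middle": [
            "i had {t2} last week and i am waiting for the result.",
            "i had {t2} last month and i am waiting for the result.",
            "i had {t2} recently and i am waiting for the report.",
            "i had {t2} last week and i am still waiting for the report.",
            "i had {t2} recently and i am waiting for the result.",
        ],
        "closer": [
            "my question is what comes next. please help me.",
            "my question is what happens next. please help me.",
            "my question is what comes next. any advice would be greatly appreciated.",
            "my question is what happens next. thanks for your replies.",
            "my question is what comes next. thanks for your replies.",
        ],
    },
    "caregiver": {
        "opener": [
            "my {kin} was diagnosed last year and now has {t1}.",
            "my {kin} was diagnosed last month and now has {t1}.",
            "my {kin} was diagnosed recently and now has {t1}.",
            "my {kin} was diagnosed last year and still has {t1}.",
            "my {kin} was diagnosed recently and still has {t1}.",
        ],
        "middle": [
            "the doctor ordered {t2} and we want to know what to expect.",
            "the doctor ordered {t2} and we want to know how long it takes.",
            "the doctor suggested {t2} and we want to know what to expect.",
            "the doctor mentioned {t2} and we want to know what to expect.",
            "the doctor suggested {t2} and we want to know how long it takes.",
        ],
        "closer": [
            "has anyone been through this? thanks so much for any advice.",
            "has anyone been through this? we would appreciate any information.",
            "has anyone seen this before? thanks so much for any advice.",
            "has anyone been through this before? thanks so much.",
            "has anyone seen this before? we would appreciate any information.",
        ],
    },
    "specialist": {
        "opener": [
            "you should discuss the {t1} with your doctor.",
            "you should discuss the {t1} with your physician.",
            "you should mention the {t1} to your doctor.",
            "you should discuss the {t1} with your specialist.",
            "you should mention the {t1} to your physician.",
        ],
        "middle": [
            "{t2} is common and usually manageable in most cases.",
            "{t2} is common and usually treatable in most cases.",
            "{t2} is quite common and usually manageable.",
            "{t2} is common and in most cases manageable.",
            "{t2} is quite common and usually treatable.",
        ],
        "closer": [
            "hope this helps. good luck.",
            "hope this helps. all the best.",
            "let us know how it goes. good luck.",
            "hope this helps. let us know how it goes.",
            "let us know how it goes. all the best.",
        ],
    },
    # Neutral pools for single-population topic corpora: fixed opener and
    # closer; all topic terms appear in one comma-separated listing
    # sentence bracketed by random day/count numbers. The mention count
    # is Poisson and each mention is an independent uniform draw from the
    # topic pool, so per-term counts are independent Poissons within a
    # topic; every n-gram adjacent to a term or number is a rare
    # combination that falls under any document-frequency floor, leaving
    # the terms themselves as the only stable topic columns.
    "member": {
        "opener": ["looking for information after my last visit."],
        "middle": ["the doctor mentioned these on day {n}: {ts}, {n2} times in total."],
        "closer": ["curious what others here have learned."],
    },
}

# Extra mentions are emitted as one listing sentence; adjacencies between
# randomly drawn terms are rare pairs, so they add no stable n-gram axis.
_EXTRA_MENTION = "we have also discussed {ts} along the way."

# Every emotional message carries exactly one clause: a frame filled with
# 2+ sentiment words drawn from the polarity's word list. The frame
# inventory is shared by all groups and the word combinations vary, so
# the emotional signal spreads thinly across many n-grams instead of
# forming its own cluster axis; intensity differs between groups only
# through the number of words per clause. Every word scores >= 0.625, so
# a two-word clause carries >= 1.25 lexicon intensity — past tau = 1.0.
EMOTION_FRAMES = [
    "i am so {words} about this.",
    "i have been so {words} about this.",
    "i am {words} about all of this.",
]
POSITIVE_WORDS = [
    "happy", "grateful", "hopeful", "relieved", "glad", "thankful",
    "joyful", "encouraged", "optimistic",
]
NEGATIVE_WORDS = [
    "scared", "worried", "sad", "anxious", "hopeless", "depressed",
    "miserable", "upset", "afraid", "overwhelmed",
]


class ForumSpec(BaseModel):
    """Per-forum member counts, posting volume and topic mixtures."""

    name: str
    members: dict[Group, int]
    messages_per_member_mean: dict[Group, float]
    topic_mixture: dict[Group, dict[str, float]]

    @model_validator(mode="after")
    def _check(self):
        problems = []
        for g, n in self.members.items():
            if n < 0:
                problems.append(f"negative member count for {g}")
            if g not in self.messages_per_member_mean:
                problems.append(f"no posting volume for {g}")
            if self.messages_per_member_mean.get(g, 1.0) < 1.0:
                problems.append(f"messages per member must be >= 1 for {g}")
            mix = self.topic_mixture.get(g)
            if mix is None:
                problems.append(f"no topic mixture for {g}")
            elif abs(sum(mix.values()) - 1.0) > 1e-6:
                problems.append(f"topic mixture for {g} does not sum to 1")
            elif any(t not in TOPICS for t in mix):
                problems.append(f"unknown topic in mixture for {g}")
        if problems:
            raise ValueError("; ".join(problems))
        return self


class GeneratorConfig(BaseModel):
    """Full description of a synthetic forum corpus."""

    seed: int = 0
    forums: list[ForumSpec]
    emotional_prob: dict[Group, float] = Field(
        default={"patient": 0.25, "caregiver": 0.14, "specialist": 0.21, "member": 0.0}
    )
    # Baseline probability that an emotional message is positive, and a
    # linear change in that probability over the author's first year.
    polarity_positive: dict[Group, float] = Field(
        default={"patient": 0.40, "caregiver": 0.38, "specialist": 0.55, "member": 0.5}
    )
    trend_pos_slope: dict[Group, float] = Field(
        default={"patient": 0.25, "caregiver": 0.25, "specialist": 0.0, "member": 0.0}
    )
    # Sentiment words per emotional clause (intensity knob, min 2).
    emotional_intensity: dict[Group, int] = Field(
        default={"patient": 2, "caregiver": 3, "specialist": 3, "member": 2}
    )
    # Extra neutral topic-term mentions appended per message.
    extra_term_mentions: int = 0
    # Whether the secondary term slot stays inside the message's topic
    # pool (strong per-message topic signal, for topic corpora) or roams
    # over the forum's whole vocabulary (realistic cross-topic asides).
    secondary_term_on_topic: bool = False
    start_date: datetime = datetime(2007, 1, 1)
    end_date: datetime = datetime(2016, 10, 31)

    @model_validator(mode="after")
    def _check(self):
        problems = []
        for name, probs in (
            ("emotional_prob", self.emotional_prob),
            ("polarity_positive", self.polarity_positive),
        ):
            for g, p in probs.items():
                if not 0.0 <= p <= 1.0:
                    problems.append(f"{name}[{g}] outside [0, 1]")
        for f in self.forums:
            pools = TOPIC_POOLS.get(f.name)
            if pools is None:
                problems.append(f"no topic pools for forum {f.name!r}")
        if self.start_date >= self.end_date:
            problems.append("start_date must precede end_date")
        if problems:
            raise ValueError("; ".join(problems))
        return self


@dataclass
class GoldLabels:
    """Planted truth for every generated unit."""

    member_group: dict[str, str] = field(default_factory=dict)  # author_id -> group
    member_forum: dict[str, str] = field(default_factory=dict)
    message_topic: dict[str, str] = field(default_factory=dict)  # message_id -> topic
    message_emotional: dict[str, bool] = field(default_factory=dict)
    message_polarity: dict[str, str | None] = field(default_factory=dict)

    def write(self, directory: str | Path) -> None:
        directory = Path(directory)
        with (directory / "gold_members.tsv").open("w") as fh:
            fh.write("author_id\tforum\tgroup\n")
            for a in sorted(self.member_group):
                fh.write(f"{a}\t{self.member_forum[a]}\t{self.member_group[a]}\n")
        with (directory / "gold_messages.tsv").open("w") as fh:
            fh.write("message_id\ttopic\temotional\tpolarity\n")
            for m in sorted(self.message_topic):
                fh.write(
                    f"{m}\t{self.message_topic[m]}\t"
                    f"{int(self.message_emotional[m])}\t"
                    f"{self.message_polarity[m] or ''}\n"
                )


def _sample_message_text(
    rng: np.random.Generator,
    group: str,
    topic: str,
    pool: list[str],
    all_terms: list[str],
    cfg: GeneratorConfig,
    days_since_first: float,
) -> tuple[str, bool, str | None]:
    pools = SENTENCE_POOLS[group]
    if group == "member":
        # Topic-corpus messages: Poisson mention count, iid uniform
        # mentions, comma-separated listing.
        # A fixed number of iid term mentions per message: constant topic
        # signal strength, no topic-ambiguous near-empty tail.
        n_mentions = 2 + max(0, cfg.extra_term_mentions)
        chosen = rng.integers(len(pool), size=n_mentions)
        middle = pools["middle"][rng.integers(len(pools["middle"]))].format(
            n=int(rng.integers(1, 361)),
            n2=int(rng.integers(1, 201)),
            ts=", ".join(pool[i] for i in chosen),
        )
        text = " ".join(
            (
                pools["opener"][rng.integers(len(pools["opener"]))],
                middle,
                pools["closer"][rng.integers(len(pools["closer"]))],
            )
        )
    else:
        term1 = pool[rng.integers(len(pool))]
        if cfg.secondary_term_on_topic:
            term2 = term1
            while term2 == term1:
                term2 = pool[rng.integers(len(pool))]
        else:
            term2 = all_terms[rng.integers(len(all_terms))]
        kin = KINSHIP_TERMS[rng.integers(len(KINSHIP_TERMS))]
        text = " ".join(
            pools[part][rng.integers(len(pools[part]))].format(
                t1=term1, t2=term2, kin=kin
            )
            for part in ("opener", "middle", "closer")
        )
        if cfg.extra_term_mentions > 0:
            n_extra = min(cfg.extra_term_mentions, len(pool))
            extra = rng.choice(len(pool), size=n_extra, replace=False)
            text += " " + _EXTRA_MENTION.format(
                ts=" and ".join(pool[i] for i in extra)
            )

    emotional = bool(rng.random() < cfg.emotional_prob.get(group, 0.0))
    polarity: str | None = None
    if emotional:
        p_pos = cfg.polarity_positive.get(group, 0.5) + cfg.trend_pos_slope.get(
            group, 0.0
        ) * min(days_since_first, 360.0) / 360.0
        p_pos = float(np.clip(p_pos, 0.05, 0.95))
        polarity = "positive" if rng.random() < p_pos else "negative"
        words = POSITIVE_WORDS if polarity == "positive" else NEGATIVE_WORDS
        n_words = max(2, cfg.emotional_intensity.get(group, 2))
        frame = EMOTION_FRAMES[rng.integers(len(EMOTION_FRAMES))]
        chosen = rng.choice(len(words), size=min(n_words, len(words)), replace=False)
        text += " " + frame.format(words=" and ".join(words[i] for i in chosen))
    return text, emotional, polarity


def generate_corpus(cfg: GeneratorConfig) -> tuple[Corpus, GoldLabels]:
    """Build a corpus and its gold labels, deterministic given cfg.seed."""
    rng = np.random.default_rng(cfg.seed)
    gold = GoldLabels()
    messages: list[Message] = []
    horizon_days = (cfg.end_date - cfg.start_date).days

    author_counter = 0
    msg_counter = 0
    for forum in cfg.forums:
        pools = TOPIC_POOLS[forum.name]
        all_terms = sorted({t for pool in pools.values() for t in pool})
        for group in sorted(forum.members):
            n_members = forum.members[group]
            mean_msgs = forum.messages_per_member_mean[group]
            mix = forum.topic_mixture[group]
            topics = sorted(mix)
            probs = np.array([mix[t] for t in topics])
            gap_mean = 12.0 if mean_msgs > 5 else 20.0
            for _ in range(n_members):
                author_id = f"u{author_counter:05d}"
                author_counter += 1
                gold.member_group[author_id] = group
                gold.member_forum[author_id] = forum.name
                # floor(mean) or one more message: hits the target mean
                # exactly with minimal spread, so posting volume separates
                # the groups without planting spurious within-group axes.
                base = int(mean_msgs)
                n_msgs = base + int(rng.random() < (mean_msgs - base))
                first_day = rng.uniform(0, max(1.0, horizon_days - 400))
                day = first_day
                for j in range(n_msgs):
                    if j > 0:
                        day += rng.exponential(gap_mean)
                    topic = topics[int(rng.choice(len(topics), p=probs))]
                    text, emotional, polarity = _sample_message_text(
                        rng, group, topic, pools[topic], all_terms, cfg,
                        day - first_day,
                    )
                    message_id = f"msg{msg_counter:06d}"
                    msg_counter += 1
                    ts = cfg.start_date + timedelta(
                        days=float(day), seconds=float(rng.integers(86400))
                    )
                    messages.append(
                        Message(message_id, author_id, forum.name, ts, text)
                    )
                    gold.message_topic[message_id] = topic
                    gold.message_emotional[message_id] = emotional
                    gold.message_polarity[message_id] = polarity

    corpus = Corpus(
        messages,
        provenance={"generator": cfg.model_dump(mode="json"), "seed": cfg.seed},
    )
    return corpus, gold


def _uniform_mixture() -> dict[str, float]:
    return {t: 1.0 / len(TOPICS) for t in TOPICS}


def preset(name: str, seed: int = 0) -> GeneratorConfig:
    """Named generator configurations.

    * ``tiny`` — 60 members in one forum, three balanced groups; seconds
      to generate and cluster.
    * ``paperlike`` — three disease forums, ~300 members, group ratios
      and posting-volume skew shaped like a real community census
      (patients ~50-68%, caregivers ~25-44%, specialists ~7-9%;
      specialists posting 10-30x more than the other groups).
    * ``topics`` — a single author population posting ~2000 informational
      messages over five topic vocabularies; the default topic corpus.
    """
    if name == "tiny":
        return GeneratorConfig(
            seed=seed,
            forums=[
                ForumSpec(
                    name="lung_cancer",
                    members={"patient": 20, "caregiver": 20, "specialist": 20},
                    messages_per_member_mean={
                        "patient": 1.5, "caregiver": 1.5, "specialist": 8.0
                    },
                    topic_mixture={
                        "patient": _uniform_mixture(),
                        "caregiver": _uniform_mixture(),
                        "specialist": _uniform_mixture(),
                    },
                )
            ],
        )
    if name == "paperlike":
        def mix(**kw):
            return {t: kw[t] for t in TOPICS}

        return GeneratorConfig(
            seed=seed,
            forums=[
                ForumSpec(
                    name="lung_cancer",
                    members={"patient": 50, "caregiver": 44, "specialist": 7},
                    messages_per_member_mean={
                        "patient": 1.15, "caregiver": 1.53, "specialist": 14.48
                    },
                    topic_mixture={
                        "patient": mix(symptom=0.32, examination=0.22, procedure=0.18,
                                       complication=0.17, drug=0.11),
                        "caregiver": mix(symptom=0.25, examination=0.20, procedure=0.20,
                                         complication=0.20, drug=0.15),
                        "specialist": _uniform_mixture(),
                    },
                ),
                ForumSpec(
                    name="diabetes",
                    members={"patient": 50, "caregiver": 42, "specialist": 9},
                    messages_per_member_mean={
                        "patient": 1.34, "caregiver": 1.48, "specialist": 20.43
                    },
                    topic_mixture={
                        "patient": mix(drug=0.32, symptom=0.22, examination=0.18,
                                       complication=0.16, procedure=0.12),
                        "caregiver": mix(drug=0.28, complication=0.22, symptom=0.18,
                                         examination=0.16, procedure=0.16),
                        "specialist": _uniform_mixture(),
                    },
                ),
                ForumSpec(
                    name="breast_cancer",
                    members={"patient": 68, "caregiver": 25, "specialist": 7},
                    messages_per_member_mean={
                        "patient": 1.55, "caregiver": 1.53, "specialist": 34.09
                    },
                    topic_mixture={
                        "patient": mix(examination=0.36, procedure=0.24, symptom=0.16,
                                       drug=0.12, complication=0.12),
                        "caregiver": mix(examination=0.30, procedure=0.28,
                                         complication=0.17, symptom=0.13, drug=0.12),
                        "specialist": _uniform_mixture(),
                    },
                ),
            ],
        )
    if name == "topics":
        return GeneratorConfig(
            seed=seed,
            secondary_term_on_topic=True,
            extra_term_mentions=2,
            forums=[
                ForumSpec(
                    name="lung_cancer",
                    members={"member": 400},
                    messages_per_member_mean={"member": 5.0},
                    topic_mixture={"member": _uniform_mixture()},
                )
            ],
        )
    raise ValueError(f"unknown preset {name!r}; expected tiny, paperlike or topics")


def write_bundle(
    corpus: Corpus, gold: GoldLabels, cfg: GeneratorConfig, out_dir: str | Path
) -> None:
    """Emit corpus JSONL + gold label TSVs + a config echo into a directory."""
    from .corpus_io import write_corpus

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    write_corpus(corpus, out_dir / "corpus.jsonl")
    gold.write(out_dir)
    (out_dir / "config.json").write_text(
        json.dumps(cfg.model_dump(mode="json"), indent=2, default=str)
    )
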