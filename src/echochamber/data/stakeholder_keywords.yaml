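# Stakeholder types and keyword lists, matched case-insensitively as
# substrings against the concatenated profile fields (authentication,
# introduction, tags).  Order matters: the first type with a hit wins;
# common_personnel is the keywordless fallback.
- type: government
  keywords: [government, police, court, judicial bureau, judicial office,
             procuratorate, commission for discipline inspection,
             political and legal committee]
- type: hospital
  keywords: [hospital]
- type: traditional_media
  keywords: [newspaper, radio, tv station, news, magazine, broadcast, daily,
             timely, weekly, monthly, morning post, evening post, channel]
- type: we_media
  keywords: [we-media, author, writer, reporter, editor, blogger,
             commentator, critic]
- type: platform_account
  keywords: [sina weibo, weibo medical and health operation, weibo secretary,
             weibo administrator, weibo rumor rebuttal, weibo politics]
- type: social_organization
  keywords: [association, public welfare]
- type: medical_company
  keywords: [vaccine manufacturer, sinovac, cansino, hualan, zhifei, kangtai,
             medical enterprise]
- type: common_company
  keywords: [company, enterprise]
- type: educational_institution
  keywords: [middle school, high school, campus, technical school]
- type: medical_personnel
  keywords: [doctor, nurse]
- type: common_personnel
  keywords: []
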