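/root/pkg/src/vnspredictprediction.pyrecording.py__init__.pynetwork.pyconfig.pypipeline.pysynthetic.pypreprocess.pyconnectivity.py                                      stats.py�S�`?譸f��         �   ������gR͟��f��         �   ~�����Q�h	�魸f��         hhse.py�bJpZ �l���f��         edfio.py��<�E>���f��         �   ���0�v�&����f��         �   �����7�e9R@⭸f��         �   ��������&;?��f��         �   ������s�?~��f��         �   i���� )羗F���f��         cli.py���{�Ҁ���f��         �   ���?h���8ﭸf��         �   ����rm�P�Ρ!��f��         4~:7 DAFKI7�4~:7 DAFKI7���� �   ��������      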