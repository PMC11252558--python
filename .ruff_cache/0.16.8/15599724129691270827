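/root/pkg/src/vnspredictrecording.pyprediction.py__init__.pynetwork.pyconfig.pysynthetic.pypreprocess.pyconnectivity.pypipeline.py                                      stats.py�S�`?�mf��         �   �������CG錺mf��          �   ������gR͟�mf��         �   S�����Q�h	��mf��         edfio.py��<�E>��mf��         �   ���.m��Ԫi�mf��          hhse.py�bJpZ �l��mf��         �   ��������&;?�mf��         �   �����2Q������mf��          �   i���� )羗F��mf��         cli.py��1H��0�^̺mf��          �   ������^��M�mf��          �   ����?h���8�mf��         ~4:7 DKFI7A�~4:7 DKFI7A���� �   ��������      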