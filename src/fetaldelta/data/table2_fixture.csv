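group,animal,sentinel,detection_1000hz,detection_4hz
H_UCO,8003,15:56:00,15:49:00,15:52:00
H_UCO,473351,13:38:00,13:28:00,13:04:00
H_UCO,473362,11:05:00,11:03:00,11:35:00
H_UCO,473376,12:36:00,12:38:00,11:59:00
H_UCO,473726,12:04:00,11:50:00,11:54:00
N_UCO,461060,12:42:00,12:31:00,12:21:00
N_UCO,473361,12:51:00,12:36:00,12:16:00
N_UCO,473352,13:17:00,12:53:00,12:06:00
N_UCO,473377,12:12:00,12:14:00,12:50:00
N_UCO,473378,13:22:00,13:09:00,12:09:00
N_UCO,473727,11:03:00,11:10:00,11:08:00
N_UCO,5054,12:53:00,11:27:00,11:19:00
N_UCO,5060,11:26:00,11:24:00,10:29:00
N_UCO,473360,13:59:00,13:52:00,11:55:00
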